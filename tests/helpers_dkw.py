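"""DKW-envelope comparison of a recovered ON curve with the configured
shifted-exponential ON-time distribution (shared by unit and acceptance
tests)."""

import numpy as np


def configured_on_cdf(sim, frames_rel):
    """P(first ON frame <= f) for f relative to S-phase entry.

    The simulator draws the ON waiting time as shift + Exp(mean) seconds
    and converts to frames with ceil(wait / dt), so the CDF at relative
    frame f is 1 - exp(-(f*dt - shift)/mean) for f*dt > shift.
    """
    eff = sim.resolved()
    t = np.asarray(frames_rel, dtype=float) * eff.frame_interval
    cdf = np.where(
        t > eff.on_shift_s,
        1.0 - np.exp(-(t - eff.on_shift_s) / eff.on_mean_s),
        0.0,
    )
    return cdf


def dkw_check(mcp_result, sim=None, alpha=0.05):
    """True when sup|F_emp - F| <= sqrt(ln(2/alpha) / (2 n))."""
    if sim is None:
        from conftest import MCP_SIM

        sim = MCP_SIM
    rep = mcp_result["replicates"][0]
    curves = rep["curves"]
    n = len(rep["traces"])
    emp = curves["on_pct"].to_numpy() / 100.0
    cdf = configured_on_cdf(sim, curves["frame"].to_numpy())
    eps = np.sqrt(np.log(2.0 / alpha) / (2.0 * n))
    return float(np.max(np.abs(emp - cdf))) <= eps
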