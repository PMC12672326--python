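"""Optional matplotlib figures: tornado, PSA scatter, CEAC."""

from __future__ import annotations

import numpy as np

from .uncertainty import CEACurve, PSAResult, TornadoEntry


def plot_tornado(entries: list[TornadoEntry], base_icur: float, ax=None,
                 top: int = 12):
    """Horizontal tornado bars around the base-case ICUR."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.4 * min(top, len(entries)) + 1))
    shown = [e for e in entries if not e.flagged][:top][::-1]
    for i, e in enumerate(shown):
        lo, hi = sorted((e.icur_at_low, e.icur_at_high))
        ax.barh(i, hi - lo, left=lo, color="#4878d0", alpha=0.8)
    ax.axvline(base_icur, color="k", lw=1)
    ax.set_yticks(range(len(shown)))
    ax.set_yticklabels([e.parameter for e in shown], fontsize=8)
    ax.set_xlabel("ICUR vs reference (USD/QALY)")
    return ax


def plot_psa_scatter(psa: PSAResult, target: str, reference: str,
                     wtp: float, ax=None):
    """Incremental cost vs incremental QALY cloud with the WTP line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    costs, qalys = psa.arrays()
    it, ir = psa.strategies.index(target), psa.strategies.index(reference)
    dq, dc = qalys[:, it] - qalys[:, ir], costs[:, it] - costs[:, ir]
    ax.scatter(dq, dc, s=6, alpha=0.4)
    xs = np.linspace(min(dq.min(), 0), dq.max(), 10)
    ax.plot(xs, wtp * xs, "r--", lw=1, label=f"WTP {wtp:,.0f}/QALY")
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (USD)")
    ax.legend()
    return ax


def plot_ceac(curve: CEACurve, ax=None):
    """Acceptability curves for every strategy."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for s, p in curve.prob_cost_effective.items():
        ax.plot(curve.wtp_grid, p, label=s, lw=1.2)
    ax.set_xlabel("Willingness-to-pay (USD/QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=7)
    return ax
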