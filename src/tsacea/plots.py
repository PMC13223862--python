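"""Figure helpers: cost-effectiveness plane, tornado diagram, CEAC.

Each function returns a matplotlib Figure; callers save or show it.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .uncertainty import PSAResult, TornadoResult

__all__ = ["ce_plane", "tornado_diagram", "ceac_curve"]


def ce_plane(psa: PSAResult):
    """Scatter of incremental (QALY, cost) draws with the WTP threshold line."""
    fig, ax = plt.subplots(figsize=(6, 5))
    dq = psa.draws["delta_qaly"]
    dc = psa.draws["delta_cost"]
    ax.scatter(dq, dc, s=4, alpha=0.3, linewidths=0)
    span = np.array([dq.min(), dq.max()])
    ax.plot(span, psa.wtp * span, "k--", lw=1, label=f"WTP ${psa.wtp:,.0f}/QALY")
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (USD)")
    ax.set_title("Cost-effectiveness plane")
    ax.legend()
    fig.tight_layout()
    return fig


def tornado_diagram(tornado: TornadoResult, top_n: int | None = None):
    """Horizontal bars of INMB at each parameter's range ends, widest first."""
    table = tornado.table if top_n is None else tornado.table.head(top_n)
    table = table.iloc[::-1]  # widest at top
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(table) + 1.5))
    y = np.arange(len(table))
    lo = np.minimum(table["inmb_low"], table["inmb_high"])
    hi = np.maximum(table["inmb_low"], table["inmb_high"])
    ax.barh(y, hi - lo, left=lo, color="#4878d0")
    ax.axvline(tornado.base_inmb, color="k", lw=1, label="base-case INMB")
    ax.set_yticks(y, table["parameter"])
    ax.set_xlabel("Incremental net monetary benefit (USD)")
    ax.set_title("One-way sensitivity (tornado)")
    ax.legend()
    fig.tight_layout()
    return fig


def ceac_curve(curve: pd.DataFrame):
    """Probability cost-effective as a function of willingness-to-pay."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["wtp"], curve["probability_cost_effective"], "-o", ms=3)
    ax.set_ylim(0, 1.02)
    ax.set_xlabel("Willingness-to-pay (USD/QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_title("Cost-effectiveness acceptability curve")
    fig.tight_layout()
    return fig
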