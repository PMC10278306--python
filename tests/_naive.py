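"""Independent straight-line reference implementation of the QTL peeling
procedure, used as an oracle for xqtl.qtl_caller.call_qtl.

Deliberately written as plain loops over pandas rows, sharing no code with
the package implementation.
"""
import math

import numpy as np
from scipy.stats import norm


def _pearson(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ac = a - a.mean()
    bc = b - b.mean()
    return float((ac * bc).sum() / math.sqrt((ac**2).sum() * (bc**2).sum()))


def _neglog10_two_sided(t):
    return -(math.log(2.0) + norm.logsf(abs(t))) / math.log(10.0)


def naive_call_qtl(stats, dosages_by_id, threshold=7.3, halfwidth=10_000_000, ld=0.7):
    """Six-step peeling: returns a list of dicts (lead, ci ids, iteration)."""
    remaining = stats.copy().reset_index(drop=True)
    regions = []
    iteration = 0
    while True:
        sig = remaining[remaining["neglog10p"] >= threshold]
        if sig.empty:
            break
        iteration += 1
        best = sig["neglog10p"].max()
        tied = sig[sig["neglog10p"] == best].sort_values(["pos", "id"])
        lead = tied.iloc[0]
        window = remaining[(remaining["pos"] - lead["pos"]).abs() <= halfwidth]
        x_lead = dosages_by_id[lead["id"]]
        r = {row["id"]: _pearson(x_lead, dosages_by_id[row["id"]])
             for _, row in window.iterrows()}
        ci = [row["id"] for _, row in window.iterrows() if abs(r[row["id"]]) >= ld]
        removed = set(ci)
        for _, row in window.iterrows():
            if row["id"] in removed:
                continue
            t_i = row["b"] / row["se"]
            t_new = (row["b"] - lead["b"] * r[row["id"]]) / row["se"]
            if _neglog10_two_sided(t_new) < threshold and np.sign(t_new) * np.sign(t_i) > 0:
                removed.add(row["id"])
        ci_pos = [int(window.loc[window["id"] == v, "pos"].iloc[0]) for v in ci]
        regions.append(
            {
                "lead": lead["id"],
                "lead_pos": int(lead["pos"]),
                "ci": sorted(ci),
                "ci_start": min(ci_pos),
                "ci_end": max(ci_pos),
                "iteration": iteration,
            }
        )
        remaining = remaining[~remaining["id"].isin(removed)].reset_index(drop=True)
    return regions
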