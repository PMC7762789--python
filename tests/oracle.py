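"""Independent brute-force evaluator of the six release criteria.

Deliberately written with plain Python loops, the statistics module, and
scipy.stats.pearsonr — no shared code with exorelease.release — so it can
serve as a cross-check oracle.
"""

import math
import statistics

from scipy.stats import pearsonr


def brute_force_release(table, meta, strain, noise_ratio=3.0, cv_max=20.0,
                        lfc_min=1.0, pearson_min=0.7):
    """Return {feature_id: {"c1"..: bool, "released": bool}} by direct formula."""
    meta = meta[meta["sample_id"].isin(table.sample_ids)]
    strain_rows = meta[meta["class"] == strain]
    ctrl_ids = meta.loc[meta["class"] == "external_control", "sample_id"].tolist()
    times = sorted(strain_rows["time_h"].unique())
    by_tp = {
        t: strain_rows.loc[strain_rows["time_h"] == t, "sample_id"].tolist() for t in times
    }
    out = {}
    for fid in table.feature_ids:
        row = table.data.loc[fid]
        strain_vals = [row[s] for t in times for s in by_tp[t]]
        ctrl_vals = [row[s] for s in ctrl_ids]
        tp_vals = {t: [row[s] for s in by_tp[t]] for t in times}
        tp_means = {t: statistics.mean(v) for t, v in tp_vals.items()}

        c1 = max(strain_vals) > max(ctrl_vals)

        min_last = min(tp_vals[times[-1]])
        c2 = min_last > 0 and min_last >= noise_ratio * max(ctrl_vals)

        c3 = True
        for t in times:
            v = tp_vals[t]
            if len(v) < 2:
                continue
            sd = statistics.stdev(v)
            if sd == 0:
                continue
            m = statistics.mean(v)
            cv = 100.0 * sd / m if m != 0 else math.inf
            if not cv < cv_max:
                c3 = False

        c4 = all(tp_means[t] >= tp_means[times[0]] for t in times)

        m0, mL = tp_means[times[0]], tp_means[times[-1]]
        if m0 == 0:
            c5 = mL > 0
        elif mL == 0:
            c5 = False
        else:
            c5 = math.log2(mL / m0) > lfc_min

        xs = [t for t in times for _ in by_tp[t]]
        ys = [row[s] for t in times for s in by_tp[t]]
        if len(set(ys)) < 2:
            c6 = False
        else:
            c6 = pearsonr(xs, ys)[0] >= pearson_min

        out[fid] = {
            "c1": c1, "c2": c2, "c3": c3, "c4": c4, "c5": c5, "c6": c6,
            "released": c1 and c2 and c3 and c4 and c5 and c6,
        }
    return out
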