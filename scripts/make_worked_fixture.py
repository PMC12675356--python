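"""Regenerate the committed worked fixture and its oracle manifest.

The manifest values are computed here with independent brute-force
implementations (double-loop sums of squares, pooled-ECDF scan, pair
counting, hand-built O/E/V log-rank table) — never with the package's own
statistics — so the fixture tests check the package against a second route.

Run from the repository root:  python scripts/make_worked_fixture.py
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from logitda import counts_to_log2tpm1, worked_fixture
from logitda.io import write_clinical, write_expression, write_gene_lengths

OUT = Path(__file__).resolve().parent.parent / "tests" / "fixtures" / "worked"


# ---- independent oracles -------------------------------------------------

def oracle_bw(values, response):
    x = np.asarray(values, float)
    y = np.asarray(response, int)
    grand = x.mean()
    between = within = 0.0
    for cls in (0, 1):
        grp = x[y == cls]
        between += len(grp) * (grp.mean() - grand) ** 2
        for v in grp:
            within += (v - grp.mean()) ** 2
    if within == 0:
        return float("inf") if between > 0 else 0.0
    return between / within


def oracle_ks(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    best = 0.0
    for x in np.concatenate([a, b]):
        fa = (a <= x).mean()
        fb = (b <= x).mean()
        best = max(best, abs(fa - fb))
    return best


def oracle_auc(scores, labels):
    s, y = np.asarray(scores, float), np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def oracle_logrank(ta, ea, tb, eb):
    ta, ea, tb, eb = map(np.asarray, (ta, ea, tb, eb))
    times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    O = E = V = 0.0
    for t in times:
        na = ((ta >= t)).sum()
        nb = ((tb >= t)).sum()
        da = ((ta == t) & (ea == 1)).sum()
        db = ((tb == t) & (eb == 1)).sum()
        n, d = na + nb, da + db
        if n < 2 or d == 0:
            continue
        O += da
        E += d * na / n
        V += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    chisq = (O - E) ** 2 / V
    return float(chisq)


# ---- build fixture -------------------------------------------------------

def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    sim = worked_fixture()
    write_expression(sim.train_counts, OUT / "train_counts.tsv")
    write_clinical(sim.train_clinical, OUT / "train_clinical.tsv")
    write_expression(sim.test_counts, OUT / "test_counts.tsv")
    write_clinical(sim.test_clinical, OUT / "test_clinical.tsv")
    write_gene_lengths(sim.gene_lengths, OUT / "gene_lengths.tsv")

    train_log2 = counts_to_log2tpm1(sim.train_counts, sim.gene_lengths)
    test_log2 = counts_to_log2tpm1(sim.test_counts, sim.gene_lengths)
    y = sim.train_clinical.response.to_numpy()

    bw = {g: oracle_bw(train_log2.values.loc[g].to_numpy(), y) for g in train_log2.gene_ids}
    ks = {
        g: oracle_ks(train_log2.values.loc[g].to_numpy(), test_log2.values.loc[g].to_numpy())
        for g in train_log2.gene_ids
    }
    top_bw_gene = max(bw, key=bw.get)
    auc_top = oracle_auc(train_log2.values.loc[top_bw_gene].to_numpy(), y)

    # log-rank on the median split of the first survival gene in the train cohort
    surv_gene = sorted(sim.truth.survival_genes)[0]
    vals = train_log2.values.loc[surv_gene].to_numpy()
    hi = vals >= np.median(vals)
    t = sim.train_clinical.table["os_time"].to_numpy(float)
    e = sim.train_clinical.table["os_event"].to_numpy(int)
    chisq_surv = oracle_logrank(t[hi], e[hi], t[~hi], e[~hi])

    manifest = {
        "bw_ratio": bw,
        "ks_distance": ks,
        "top_bw_gene": top_bw_gene,
        "auc_top_bw_gene": auc_top,
        "survival_gene": surv_gene,
        "logrank_chisq_survival_gene": chisq_surv,
        "canonical_logrank_example": {
            "times_a": [1, 2], "events_a": [1, 1],
            "times_b": [3, 4], "events_b": [1, 1],
            "chisq": 49.0 / 17.0,
        },
        "truth": sim.truth.as_dict(),
    }
    with open(OUT / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    print(f"wrote fixture + manifest to {OUT}")
    print(f"top BW gene {top_bw_gene} (BW={bw[top_bw_gene]:.4f}, AUC={auc_top:.4f})")
    print(f"survival gene {surv_gene} log-rank chisq={chisq_surv:.4f}")


if __name__ == "__main__":
    main()
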