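"""Pool each measure's 99 per-dataset effects by random-effects meta-analysis.

Reads results/study/effects.tsv, fits the REML normal-normal model per
measure, and reports how many pooled ("true") effects are significant at
p <= .05 and at the Bonferroni level .05/70 — the split that decides which
branch of the reproduction criterion each effect follows.
"""

import argparse

from asymrepro.io import read_summary_table
from asymrepro.meta import random_effects_meta
from asymrepro.pipeline import meta_table
from asymrepro.reproducibility import group_by_measure


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--input", default="results/study/effects.tsv")
    parser.add_argument("--method", default="REML", choices=["DL", "REML", "FE"])
    parser.add_argument("--out", default="results/meta.tsv")
    args = parser.parse_args()

    records, _ = read_summary_table(args.input)
    metas = {
        m: random_effects_meta(recs, method=args.method)
        for m, recs in group_by_measure(records).items()
    }
    table = meta_table(metas)
    import pathlib

    pathlib.Path(args.out).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, sep="\t", index=False)

    m = len(table)
    print(f"pooled {m} measures over k = {table.k.iloc[0]} datasets "
          f"({args.method} tau2)")
    print(f"significant at p<=.05:      {(table.p <= 0.05).sum()} of {m}")
    print(f"significant at p<=.05/{m}: {(table.p <= 0.05 / m).sum()} of {m}")
    print(f"median tau2: {table.tau2.median():.4f}; "
          f"|pooled d| range {table.pooled_d.abs().min():.4f}-"
          f"{table.pooled_d.abs().max():.2f}")


if __name__ == "__main__":
    main()
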