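"""Resampling sensitivity: does significance survive smaller samples?

Repeats the PGLS regression on random tip subsamples of the synthetic
phylogeny and tallies how often the slope is significantly positive,
nonsignificant, or significantly negative.  At a weak evolutionary
correlation the positive-significant rate climbs steeply with the
subsample size m — the sample-sizes-matter effect — while under the null
the significance rate stays near the nominal 5%.
"""

from pathlib import Path

import pandas as pd

import thermogc as tg
from thermogc.contrasts import resample_pgls

BASE = Path(__file__).resolve().parent.parent / "results"
SYN = BASE / "synthetic"
ROUNDS = 200
SEED = 7


def main() -> None:
    tree = tg.read_newick((SYN / "tree.nwk").read_text())
    rows = []
    for name in ("weak", "strong", "null"):
        traits = pd.read_csv(SYN / f"traits_{name}.tsv", sep="\t", index_col=0)
        for m in (40, 80, 150):
            tally = resample_pgls(tree, traits, [("GC", "Topt")], m=m,
                                  rounds=ROUNDS, seed=SEED)
            c = tally.counts.loc["GC~Topt"]
            rows.append({"dataset": name, "m": m, "rounds": ROUNDS,
                         "negative": c["negative"],
                         "nonsignificant": c["nonsignificant"],
                         "positive": c["positive"]})
            print(f"{name:6s} m={m:3d}: -/ns/+ = {c['negative']}/"
                  f"{c['nonsignificant']}/{c['positive']}")
    df = pd.DataFrame(rows)
    df.to_csv(BASE / "resampling_tally.tsv", sep="\t", index=False)
    weak = df[df.dataset == "weak"].set_index("m")["positive"]
    print(f"weak correlation: positive-significant rises "
          f"{weak[40]}/{ROUNDS} -> {weak[150]}/{ROUNDS} as m grows: "
          f"small subsamples routinely miss a real association.")


if __name__ == "__main__":
    main()
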