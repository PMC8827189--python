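"""Nonlinearity of the GC-Topt relationship via penalized splines.

Fits GC ~ b0 + s(Topt) + (1|genus) on the synthetic traits (genus labels
derived from the deepest clades so related tips share a group) and on two
reference shapes — pure linear and sinusoidal — to anchor the effective
degrees of freedom (edf) scale: edf near 1 means the relationship is
linear, larger values measure increasing curvature.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import thermogc as tg
from thermogc.nonlinearity import fit_gamm

BASE = Path(__file__).resolve().parent.parent / "results"
SYN = BASE / "synthetic"


def _genus_from_clades(tree: tg.PhyloTree, size: int = 8) -> pd.Series:
    """Group tips by their ancestral clade of roughly the given size."""
    genus = {}
    counter = 0
    for nd in tree._tree.postorder_node_iter():
        if nd.is_leaf():
            continue
        tips = [tree.tip_labels[i] for i in nd._tgc_tips]
        if len(tips) <= size and not any(t in genus for t in tips):
            for t in tips:
                genus[t] = f"clade{counter}"
            counter += 1
    for t in tree.tip_labels:
        genus.setdefault(t, f"single_{t}")
    return pd.Series(genus)


def main() -> None:
    tree = tg.read_newick((SYN / "tree.nwk").read_text())
    traits = pd.read_csv(SYN / "traits_strong.tsv", sep="\t", index_col=0)
    genus = _genus_from_clades(tree).loc[traits.index]

    rows = []
    fit = fit_gamm(traits["Topt"], traits["GC"], genus.to_numpy())
    rows.append({"dataset": "synthetic GC~Topt", "edf": fit.edf,
                 "P_smooth": fit.smooth_pvalue, "genus_sd": fit.genus_sd})
    print(f"GC ~ s(Topt) + (1|genus): edf = {fit.edf:.2f} "
          f"(P = {fit.smooth_pvalue:.3g}, genus sd = {fit.genus_sd:.2f})")
    pd.DataFrame({"Topt": fit.grid_x, "fit": fit.grid_fit}).to_csv(
        BASE / "gamm_curve.tsv", sep="\t", index=False)

    r = np.random.default_rng(0)
    x = r.uniform(0, 100, 500)
    lin = 40 + 0.2 * x + r.normal(0, 2, 500)
    sin = 50 + 8 * np.sin(x / 10) + r.normal(0, 2, 500)
    for name, y in (("linear reference", lin), ("sinusoidal reference", sin)):
        f = fit_gamm(x, y, np.zeros(500, dtype=int))
        rows.append({"dataset": name, "edf": f.edf, "P_smooth": f.smooth_pvalue,
                     "genus_sd": f.genus_sd})
        print(f"{name}: edf = {f.edf:.2f}")
    pd.DataFrame(rows).to_csv(BASE / "gamm_summary.tsv", sep="\t", index=False)
    print("edf near 1 flags a linear association; the sinusoidal reference "
          "shows what strong nonlinearity looks like on the same scale.")


if __name__ == "__main__":
    main()
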