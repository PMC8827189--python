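"""PGLS regressions of GC on Topt under four trait-evolution models.

Fits Brownian motion, Pagel's lambda, fixed-root Ornstein-Uhlenbeck and
early-burst covariances to the strongly correlated synthetic traits,
compares AIC, adds a binary-covariate multiple regression (the
domain-style 0/1 predictor), and applies Benjamini-Hochberg adjustment
within the declared family of tests.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import thermogc as tg
from thermogc.stats import bh_adjust

BASE = Path(__file__).resolve().parent.parent / "results"
SYN = BASE / "synthetic"


def main() -> None:
    tree = tg.read_newick((SYN / "tree.nwk").read_text())
    traits = pd.read_csv(SYN / "traits_strong.tsv", sep="\t", index_col=0)
    rows = []
    for model in ("BM", "lambda", "OU_fixed_root", "EB"):
        fit = tg.pgls(tree, traits["GC"], traits["Topt"], model=model,
                      names=["Topt"])
        rows.append({"model": model, "slope": fit.coef["Topt"],
                     "SE": fit.se["Topt"], "t": fit.tvals["Topt"],
                     "P": fit.pvals["Topt"], "param": fit.param,
                     "AIC": fit.aic, "n": fit.n})
    df = pd.DataFrame(rows).set_index("model")
    df["P_BH"] = bh_adjust(df["P"])
    df.to_csv(BASE / "pgls_four_models.tsv", sep="\t")
    print(df[["slope", "P", "P_BH", "AIC"]].round(4))
    best = df["AIC"].idxmin()
    print(f"lowest AIC: {best}; slopes agree across models, as they should "
          f"when the generating process is Brownian.")

    # multiple regression with a 0/1 covariate (domain-style)
    rng = np.random.default_rng(1)
    design = pd.DataFrame({
        "Topt": traits["Topt"],
        "domain": rng.integers(0, 2, len(traits)).astype(float)},
        index=traits.index)
    mfit = tg.pgls(tree, traits["GC"], design, model="lambda")
    print(f"multiple PGLS: slope(Topt) = {mfit.coef['Topt']:.4f} "
          f"(P = {mfit.pvals['Topt']:.2g}), slope(domain) = "
          f"{mfit.coef['domain']:.4f} (P = {mfit.pvals['domain']:.2g}) "
          f"- the uninformative covariate stays nonsignificant.")


if __name__ == "__main__":
    main()
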