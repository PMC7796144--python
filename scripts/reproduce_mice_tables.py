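"""Reproduce the colorectal-tissue Raman analysis tables from the public
Zenodo deposit ("Raman spectra of colon cancer in a mice model",
https://zenodo.org/record/3975464).

Requires a local copy of the deposit (not shipped here): a response CSV of
485 mean spectra x 696 wavenumbers and a design CSV with the factors
individual (47 mice), location (colon/rectum), p53 (active/inactive) and
gender (male/female).  Computes, for classical ASCA, ASCA+ (deviation
coding) and WE-ASCA:

  * the percent-variance table per effect under the model
    individual + location + p53 + gender + location:p53 + location:gender
    + p53:gender,
  * the first-two-PC shares of the whole-data PCA and of each effect
    sub-model.

Usage:
    python scripts/reproduce_mice_tables.py RESPONSE.csv DESIGN.csv
"""

from __future__ import annotations

import sys

import pandas as pd

from weasca import (
    ModelSpec,
    classical_asca_decompose,
    decompose,
    fit_effect_submodel,
    naive_percent_variance,
    type3_percent_variance,
    whole_data_pca,
)
from weasca.cli_io import read_dataset

MODEL = (
    "individual + location + p53 + gender + location:p53 "
    "+ location:gender + p53:gender"
)


def main(response_path: str, design_path: str) -> None:
    X, design = read_dataset(response_path, design_path)
    print(f"loaded {X.shape[0]} spectra x {X.shape[1]} wavenumbers")

    rows = {}
    cl = classical_asca_decompose(X, design, ModelSpec.from_formula(MODEL))
    vp_cl = naive_percent_variance(cl)
    rows["ASCA"] = {**vp_cl.percent, "residual": vp_cl.residual_percent,
                    "sum": vp_cl.sum_percent}
    for label, coding in (("ASCA+", "deviation"), ("WE-ASCA", "we")):
        vp = type3_percent_variance(
            X, design, ModelSpec.from_formula(MODEL, coding=coding)
        )
        rows[label] = {**vp.percent, "residual": vp.residual_percent,
                       "sum": vp.sum_percent}
    print("\nPercent variance per effect:")
    print(pd.DataFrame(rows).T.round(2).to_string())

    wd = whole_data_pca(X, k=2)
    print(
        f"\nAll-data PCA: PC1+PC2 = {wd.explained_percent[:2].sum():.2f}%"
    )
    for label, coding in (("ASCA+", "deviation"), ("WE-ASCA", "we")):
        dec = decompose(X, design, ModelSpec.from_formula(MODEL, coding=coding))
        for term in ("individual", "location", "location:p53", "location:gender"):
            sm = fit_effect_submodel(dec.contributions[term], k=2, term=term)
            pcs = ", ".join(f"{v:.2f}" for v in sm.explained_percent[:2])
            print(f"{label:8s} {term:16s} PC shares: {pcs}")


if __name__ == "__main__":
    if len(sys.argv) != 3:
        sys.exit(__doc__)
    main(sys.argv[1], sys.argv[2])
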