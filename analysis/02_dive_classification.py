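"""Classify the located dives against bathymetry and summarize the seasonal
shift in dive types: monthly class composition, the month-dependent
multinomial model selection, and agreement with the simulated truth."""

import warnings

import pandas as pd

from common import get_run, write_table
from sealdive import models as M
from sealdive import pipeline as P


def main() -> None:
    res, tracks, classified = get_run()

    agr = P.class_agreement(classified["dive_class"],
                            res.truth.dives["dive_class"])
    print(f"dive-class agreement with truth: {agr:.4f}")

    df = classified.copy()
    df["month"] = df["start"].dt.tz_convert("UTC").dt.month
    comp = (df.groupby(["month", "dive_class"]).size()
              .unstack(fill_value=0).reset_index())
    comp["agreement"] = [
        P.class_agreement(df.loc[df["month"] == m, "dive_class"],
                          res.truth.dives.loc[(df["month"] == m).to_numpy(),
                                              "dive_class"])
        for m in comp["month"]]
    write_table(comp, "dive_classes_by_month.csv")

    known = df[df["dive_class"] != "unclassified"].copy()
    known["year"] = known["start"].dt.year.astype(str)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, best, pframe = M.fit_dive_type_multinomial(
            known, candidates=((), ("month",)))
    write_table(table, "dive_type_model_selection.csv")
    write_table(pframe, "dive_type_probabilities.csv")


if __name__ == "__main__":
    main()
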