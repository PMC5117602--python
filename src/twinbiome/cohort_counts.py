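"""Phenotype bookkeeping: cross-tabulation of ABO, secretor status and sex.

Ships the published ABO x secretor x sex cell counts of the UK adult twin
registry cohort (1503 genotype-phenotyped individuals) as a plain TSV and
recomputes every marginal from them with the same counting code used on
simulated cohorts.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

ABO_CLASSES = ("A", "AB", "B", "O")


def load_published_phenotype_counts() -> pd.DataFrame:
    """Long-format (abo, secretor, sex, count) table of the published
    cohort phenotype cells."""
    ref = resources.files("twinbiome.data") / "twinsuk_phenotype_counts.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def expand_to_individuals(counts: pd.DataFrame) -> pd.DataFrame:
    """One row per individual from a long-format cell-count table."""
    reps = counts.loc[counts.index.repeat(counts["count"])]
    return reps.drop(columns="count").reset_index(drop=True)


def phenotype_crosstab(cohort: pd.DataFrame,
                       abo_col: str = "abo",
                       secretor_col: str = "secretor",
                       sex_col: str = "sex") -> pd.DataFrame:
    """Cell counts of ABO x secretor x sex from per-individual metadata."""
    return (cohort.groupby([abo_col, secretor_col, sex_col], observed=True)
            .size().rename("count").reset_index())


def phenotype_margins(cohort: pd.DataFrame,
                      abo_col: str = "abo",
                      secretor_col: str = "secretor") -> dict[str, int]:
    """Marginal phenotype counts of a per-individual table.

    Includes per-ABO totals, secretor-status totals, and per-ABO counts
    restricted to individuals with known secretor status (the sample sizes
    entering within-class secretor comparisons).
    """
    abo = cohort[abo_col]
    sec = cohort[secretor_col]
    known = sec.isin(["S", "NS"])
    out: dict[str, int] = {"total_n": int(len(cohort))}
    for cls in ABO_CLASSES:
        out[f"n_{cls}"] = int((abo == cls).sum())
        out[f"n_{cls}_known_secretor"] = int(((abo == cls) & known).sum())
    out["n_secretor"] = int((sec == "S").sum())
    out["n_nonsecretor"] = int((sec == "NS").sum())
    out["n_secretor_unknown"] = int((~known).sum())
    return out
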