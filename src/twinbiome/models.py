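"""The nine twin-LMM association models (m1-m9) and their scans.

Each model tests residual taxon abundance against a fixed-effect contrast of
ABO and/or secretor phenotype, with random intercepts for family and for MZ
pair, and is compared to a reduced model containing only the random effects
(plus any adjustment covariates) by a likelihood-ratio test:

    m1  ABO indicators A, AB, B (baseline O)
    m2  indicator O
    m3  indicator B
    m4  indicator (B or AB)
    m5  indicator secretor
    m6  m1 restricted to secretors
    m7  m3 restricted to secretors
    m8  ABO x secretor interaction (A, AB, B, S, and products)
    m9  B, S, and B x S

q-values are computed within each model across its taxa (a global variant
across all models is also reported). Variants: ancestry-PC adjustment adds
the top genotype PCs to both full and reduced models; the LCT-adjusted scan
adds an rs1446585 dosage term to both (for Bifidobacterium-type taxa whose
abundance tracks lactase-persistence variants).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fdr import qvalues
from .lmm import TwinDesign, build_design
from .permutation import PermutationPlan, permute_phenotypes

MODEL_IDS = tuple(f"m{i}" for i in range(1, 10))


@dataclass(frozen=True)
class ModelSpec:
    """One model's fixed-effect contrast and analysis subset."""

    model_id: str
    secretors_only: bool
    uses_abo: bool
    uses_secretor: bool


_SPECS = {
    "m1": ModelSpec("m1", False, True, False),
    "m2": ModelSpec("m2", False, True, False),
    "m3": ModelSpec("m3", False, True, False),
    "m4": ModelSpec("m4", False, True, False),
    "m5": ModelSpec("m5", False, False, True),
    "m6": ModelSpec("m6", True, True, False),
    "m7": ModelSpec("m7", True, True, False),
    "m8": ModelSpec("m8", False, True, True),
    "m9": ModelSpec("m9", False, True, True),
}


def model_subset(model_id: str, abo: pd.Series,
                 secretor: pd.Series) -> pd.Index:
    """Samples entering a model: non-missing phenotypes it uses, restricted
    to secretors for m6/m7."""
    spec = _SPECS[model_id]
    ok = pd.Series(True, index=abo.index)
    if spec.uses_abo:
        ok &= ~abo.isin(["missing"]) & abo.notna()
    if spec.uses_secretor or spec.secretors_only:
        ok &= ~secretor.isin(["unknown"]) & secretor.notna()
    if spec.secretors_only:
        ok &= secretor == "S"
    return abo.index[ok]


def model_fixed_effects(model_id: str, abo: pd.Series,
                        secretor: pd.Series) -> pd.DataFrame:
    """Model-specific fixed-effect columns (no intercept) on the model's
    analysis subset."""
    idx = model_subset(model_id, abo, secretor)
    a = abo.loc[idx]
    s = (secretor.loc[idx] == "S").astype(float)
    cols: dict[str, np.ndarray] = {}
    if model_id in ("m1", "m6"):
        cols = {"A": (a == "A").astype(float),
                "AB": (a == "AB").astype(float),
                "B": (a == "B").astype(float)}
    elif model_id == "m2":
        cols = {"O": (a == "O").astype(float)}
    elif model_id in ("m3", "m7"):
        cols = {"B": (a == "B").astype(float)}
    elif model_id == "m4":
        cols = {"B_or_AB": a.isin(["B", "AB"]).astype(float)}
    elif model_id == "m5":
        cols = {"S": s}
    elif model_id == "m8":
        cols = {"A": (a == "A").astype(float),
                "AB": (a == "AB").astype(float),
                "B": (a == "B").astype(float), "S": s}
        for lvl in ("A", "AB", "B"):
            cols[f"S_x_{lvl}"] = cols[lvl] * s
    elif model_id == "m9":
        cols = {"B": (a == "B").astype(float), "S": s}
        cols["S_x_B"] = cols["B"] * s
    else:
        raise ValueError(f"unknown model {model_id!r}")
    return pd.DataFrame(cols, index=idx)


def _drop_constant(x: pd.DataFrame, context: str) -> pd.DataFrame:
    const = [c for c in x.columns if x[c].nunique() <= 1 and c != "intercept"]
    if const:
        warnings.warn(f"{context}: dropping constant columns {const}",
                      stacklevel=3)
        x = x.drop(columns=const)
    return x


def _reduced_design(idx: pd.Index,
                    extra: pd.DataFrame | None) -> pd.DataFrame:
    base = {"intercept": np.ones(len(idx))}
    if extra is not None:
        for c in extra.columns:
            base[c] = extra.loc[idx, c].values.astype(float)
    return _drop_constant(pd.DataFrame(base, index=idx), "reduced model")


def _fit_one_model(y: pd.Series, fx: pd.DataFrame,
                   extra: pd.DataFrame | None, design: TwinDesign,
                   reduced_fit=None) -> tuple[float, int, float, dict]:
    """LRT of fx columns on top of intercept+extra; ``reduced_fit`` may be
    a precomputed reduced-model LmmFit for this (subset, taxon)."""
    from .lmm import fit_lmm, lrt

    idx = fx.index
    x_red = _reduced_design(idx, extra)
    x_full = pd.concat([x_red, fx], axis=1)
    try:
        full = fit_lmm(y.loc[idx].values, x_full, design)
        if reduced_fit is None:
            reduced_fit = fit_lmm(y.loc[idx].values, x_red, design)
        df = x_full.shape[1] - x_red.shape[1]
        stat, p = lrt(full, reduced_fit, df)
        if not (full.converged and reduced_fit.converged):
            p = np.nan
        est = {k: float(v) for k, v in full.beta.items()
               if k in fx.columns}
        return stat, df, p, est
    except (np.linalg.LinAlgError, ValueError) as exc:  # non-convergence
        warnings.warn(f"model fit failed: {exc}", stacklevel=3)
        return np.nan, fx.shape[1], np.nan, {}


def run_taxa_scan(residuals: pd.DataFrame, cohort: pd.DataFrame,
                  abo: pd.Series, secretor: pd.Series,
                  model_ids=MODEL_IDS,
                  ancestry_pcs: pd.DataFrame | None = None,
                  extra_covariate: pd.Series | None = None) -> pd.DataFrame:
    """LRT of every taxon under every requested model.

    ``residuals`` is the covariate-residualized Box-Cox abundance matrix
    (samples x taxa). ``ancestry_pcs`` and/or ``extra_covariate`` (e.g. an
    LCT dosage) enter both full and reduced models. Returns a long table
    (taxon, model, stat, df, p, q, q_global, n_used, estimates) with
    q-values per model across taxa.
    """
    if residuals.shape[1] == 0:
        raise ValueError("empty taxon set")
    extra = None
    parts = []
    if ancestry_pcs is not None:
        parts.append(ancestry_pcs)
    if extra_covariate is not None:
        if extra_covariate.nunique() <= 1:
            warnings.warn("extra covariate is constant; dropped",
                          stacklevel=2)
        else:
            parts.append(extra_covariate.to_frame())
    if parts:
        extra = pd.concat(parts, axis=1).reindex(residuals.index)

    rows = []
    # reduced fits depend only on the analysis subset, so models sharing a
    # subset (m1-m4; m6+m7; m8+m9) share them per taxon
    red_cache: dict[tuple, object] = {}
    from .lmm import fit_lmm

    for model_id in model_ids:
        fx = model_fixed_effects(model_id, abo, secretor)
        fx = fx.loc[fx.index.intersection(residuals.index)]
        fx = _drop_constant(fx, model_id)
        if fx.shape[1] == 0:
            warnings.warn(f"{model_id}: no informative fixed effects; "
                          "skipped", stacklevel=2)
            continue
        design = build_design(cohort.loc[fx.index])
        subset_key = hash(tuple(fx.index))
        x_red = _reduced_design(fx.index, extra)
        for taxon in residuals.columns:
            y = residuals[taxon]
            key = (subset_key, taxon)
            if key not in red_cache:
                try:
                    red_cache[key] = fit_lmm(y.loc[fx.index].values,
                                             x_red, design)
                except (np.linalg.LinAlgError, ValueError):
                    red_cache[key] = None
            stat, df, p, est = _fit_one_model(
                y, fx, extra, design, reduced_fit=red_cache[key])
            rows.append({"taxon": taxon, "model": model_id, "stat": stat,
                         "df": df, "p": p, "n_used": len(fx),
                         "estimates": est})
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for model_id in out["model"].unique():
        mask = (out["model"] == model_id) & out["p"].notna()
        if mask.any():
            out.loc[mask, "q"] = qvalues(out.loc[mask, "p"].values)
    ok = out["p"].notna()
    out.loc[ok, "q_global"] = qvalues(out.loc[ok, "p"].values)
    return out


def bifido_lct_scan(residuals: pd.DataFrame, cohort: pd.DataFrame,
                    abo: pd.Series, secretor: pd.Series,
                    lct_dosage: pd.Series,
                    model_ids=MODEL_IDS) -> pd.DataFrame:
    """Rerun the models on designated (bifidobacterial) taxa with an LCT
    genotype dosage (0/1/2) in both full and reduced models."""
    if residuals.shape[1] == 0:
        raise ValueError("empty taxon set for LCT-adjusted scan")
    lct = lct_dosage.rename("rs1446585").astype(float)
    return run_taxa_scan(residuals, cohort, abo, secretor, model_ids,
                         extra_covariate=lct)


# ---------------------------------------------------------------------------
# alpha-diversity models

def alpha_models(alpha_residuals: pd.DataFrame, cohort: pd.DataFrame,
                 abo: pd.Series, secretor: pd.Series) -> pd.DataFrame:
    """Association of residualized alpha metrics with phenotype.

    Per metric: m1 (ABO), m5 (secretor), m6 (ABO in secretors), plus one
    within-class secretor model per ABO class (fixed effect S, same random
    effects). Classes without both secretor levels are skipped with a
    warning.
    """
    rows = []
    for metric in alpha_residuals.columns:
        y = alpha_residuals[metric]
        for model_id in ("m1", "m5", "m6"):
            fx = model_fixed_effects(model_id, abo, secretor)
            fx = fx.loc[fx.index.intersection(y.index)]
            fx = _drop_constant(fx, model_id)
            if fx.shape[1] == 0:
                continue
            design = build_design(cohort.loc[fx.index])
            stat, df, p, est = _fit_one_model(y, fx, None, design)
            rows.append({"metric": metric, "model": model_id,
                         "abo_class": "", "stat": stat, "df": df, "p": p,
                         "n_used": len(fx)})
        for cls in ("A", "AB", "B", "O"):
            idx = y.index[(abo.reindex(y.index) == cls)
                          & ~secretor.reindex(y.index).isin(["unknown"])
                          & secretor.reindex(y.index).notna()]
            s = (secretor.loc[idx] == "S").astype(float)
            if s.nunique() < 2:
                warnings.warn(f"ABO class {cls}: fewer than 2 secretor "
                              "levels; skipped", stacklevel=2)
                continue
            fx = pd.DataFrame({"S": s}, index=idx)
            design = build_design(cohort.loc[idx])
            stat, df, p, est = _fit_one_model(y, fx, None, design)
            rows.append({"metric": metric, "model": "within_class_secretor",
                         "abo_class": cls, "stat": stat, "df": df, "p": p,
                         "n_used": len(idx)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# presence/absence scan

def _chi2_stats(binary: np.ndarray, group_codes: np.ndarray,
                n_groups: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Pearson chi-squared (no continuity correction) of each
    binary column against a categorical grouping; returns (stats,
    min expected cell count)."""
    n = binary.shape[0]
    g = np.zeros((n, n_groups))
    g[np.arange(n), group_codes] = 1.0
    n_g = g.sum(axis=0)                      # (k,)
    pres = binary.T @ g                      # (m, k)
    absn = n_g[None, :] - pres
    p_pres = binary.mean(axis=0)             # (m,)
    e_pres = np.outer(p_pres, n_g)
    e_abs = np.outer(1 - p_pres, n_g)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = ((pres - e_pres) ** 2 / e_pres
                + (absn - e_abs) ** 2 / e_abs).sum(axis=1)
    min_exp = np.minimum(e_pres, e_abs).min(axis=1)
    return chi2, min_exp


def presence_absence_scan(binary: pd.DataFrame, phenotype: pd.Series,
                          plan: PermutationPlan,
                          n_perm: int = 1000) -> pd.DataFrame:
    """Chi-squared tests of OTU presence against a categorical phenotype,
    with twin-aware permutation p-values.

    Constant OTUs (all present or all absent on the analysis subset) are
    excluded with a warning. The analytic chi-squared p is reported for
    diagnostics and flagged unreliable when any expected cell count is
    below 5; the permutation p (ties count as extreme) is primary.
    """
    from .permutation import included_mask

    mask = included_mask(plan)
    idx = pd.Index(plan.samples)[mask]
    pheno = phenotype.reindex(plan.samples)
    b = binary.reindex(plan.samples).loc[idx]
    keep = [c for c in b.columns if 0 < b[c].sum() < len(b)]
    dropped = set(b.columns) - set(keep)
    if dropped:
        warnings.warn(f"{len(dropped)} constant OTUs excluded", stacklevel=2)
    b = b[keep]
    bv = b.values.astype(float)
    codes, levels = pd.factorize(pheno[mask].values)
    if len(levels) < 2:
        raise ValueError("phenotype has fewer than 2 levels")
    k = len(levels)
    obs, min_exp = _chi2_stats(bv, codes, k)
    df = k - 1
    exceed = np.zeros(len(keep))
    for d in range(n_perm):
        perm = permute_phenotypes(pheno, plan, d)
        pcodes = pd.Categorical(perm[mask], categories=levels).codes
        null, _ = _chi2_stats(bv, pcodes, k)
        exceed += null >= obs - 1e-12
    perm_p = exceed / n_perm
    out = pd.DataFrame({
        "taxon": keep,
        "chi2": obs,
        "df": df,
        "analytic_p": stats.chi2.sf(obs, df),
        "analytic_reliable": min_exp >= 5,
        "perm_p": perm_p,
    })
    out["q"] = qvalues(out["perm_p"].values)
    return out
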