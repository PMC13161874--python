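"""Focused frontoparietal (4x4) analysis.

Works on the collapsed {Ipsi FPC, Ipsi ALL, Contra FPC, Contra ALL} view:
stepwise build-toward-maximal model selection with backward likelihood-
ratio pruning, marginal-means group contrasts between clinically normal
(MoCA >= 26) and abnormal (MoCA < 26) patients, and the per-pair
between-visit connectivity increase test.

The long-format design frame has one row per subject x visit x trial x
ordered region pair with columns ``subject``, ``visit`` (categorical "1"/
"2"), ``pair`` (e.g. ``"Contra FPC -> Contra ALL"``), ``count``, ``moca``
(the MoCA score at that row's visit) plus the subject covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .glmm import ModelSpec, ZipGlmmFit, fit_zip_batch, fit_zip_glmm, likelihood_ratio_test
from .links import RegionPairCounts

__all__ = [
    "MOCA_CUTOFF",
    "MAXIMAL_TERMS",
    "moca_group",
    "fpc_design",
    "SelectionTrace",
    "SelectionError",
    "build_model",
    "marginal_means_contrasts",
    "visitwise_increase_test",
]

MOCA_CUTOFF = 26

#: Default maximal model for the build-toward-maximal procedure:
#: region-pair x visit x MoCA interactions plus the demographic and
#: stroke confounders, with the per-subject random intercept held fixed.
MAXIMAL_TERMS = (
    "pair",
    "visit",
    "moca",
    "pair:visit",
    "pair:moca",
    "visit:moca",
    "pair:visit:moca",
    "age",
    "sex",
    "race",
    "education_years",
    "lesion_hemisphere",
)


def moca_group(score):
    """Classify MoCA scores: < 26 is "abnormal", >= 26 "clinically normal".

    Accepts scalars or arrays; scores must lie in [0, 30].
    """
    arr = np.asarray(score)
    if np.any((arr < 0) | (arr > 30)):
        raise ValueError("MoCA score must be in [0, 30]")
    out = np.where(arr < MOCA_CUTOFF, "abnormal", "normal")
    return out.item() if np.ndim(score) == 0 else out


def fpc_design(counts: RegionPairCounts, cohort: pd.DataFrame) -> pd.DataFrame:
    """Long-format 4x4 design frame joining counts with subject covariates."""
    long = counts.to_long()
    long["pair"] = long["src_region"] + " -> " + long["dst_region"]
    out = long.merge(cohort, on="subject", how="left", validate="many_to_one")
    if out["moca_visit1"].isna().any():
        missing = sorted(set(long["subject"]) - set(cohort["subject"]))
        raise KeyError(f"subjects missing from cohort: {missing}")
    out["moca"] = np.where(
        out["visit"] == 1, out["moca_visit1"], out["moca_visit2"]
    ).astype(float)
    out["visit"] = out["visit"].astype(str)
    return out


@dataclass
class SelectionTrace:
    """Complete, replayable record of the stepwise selection."""

    decisions: list = field(default_factory=list)
    final_terms: tuple = ()

    def add(self, term: str, action: str, **info) -> None:
        self.decisions.append({"term": term, "action": action, **info})

    def to_dict(self) -> dict:
        return {"decisions": self.decisions, "final_terms": list(self.final_terms)}


class SelectionError(RuntimeError):
    def __init__(self, message: str, trace: SelectionTrace):
        super().__init__(message)
        self.trace = trace


def _subterms(term: str) -> set[str]:
    parts = term.split(":")
    if len(parts) == 1:
        return set()
    out = set()
    for k in range(1, len(parts)):
        from itertools import combinations

        for combo in combinations(parts, k):
            out.add(":".join(combo))
    return out


def build_model(
    maximal_terms,
    data: pd.DataFrame,
    *,
    response: str = "count",
    group: str = "subject",
    zero_inflation: str = "constant",
    n_nodes: int = 5,
    alpha: float = 0.05,
) -> tuple[ModelSpec, SelectionTrace, ZipGlmmFit]:
    """Build-toward-maximal stepwise selection with backward LRT pruning.

    Forward phase: starting from the intercept-plus-random-intercept
    model, repeatedly add the eligible candidate term with the largest
    marginal log-likelihood gain (eligible = all its lower-order
    sub-terms among the candidates are already in; a term whose fit fails
    to converge is skipped).  Backward phase: repeatedly drop the least
    significant removable term with LRT p >= ``alpha`` until every
    remaining term is significant.  The random intercept is never pruned.

    Returns the selected spec, the decision trace, and the final fit.
    """
    maximal_terms = list(maximal_terms)
    if not maximal_terms:
        raise ValueError("maximal term list must be non-empty")

    def fit(terms):
        spec = ModelSpec(
            response=response,
            fixed_terms=tuple(terms),
            random_intercept_group=group,
            zero_inflation=zero_inflation,
        )
        return spec, fit_zip_glmm(spec, data, n_nodes=n_nodes)

    trace = SelectionTrace()
    base_spec, base_fit = fit([])
    if not base_fit.converged:
        raise SelectionError("intercept-only model failed to converge", trace)

    current: list[str] = []
    current_fit = base_fit
    candidates = list(maximal_terms)
    skipped: set[str] = set()
    order = 0
    while True:
        eligible = [
            t
            for t in candidates
            if all(s in current or s not in maximal_terms for s in _subterms(t))
        ]
        best = None
        for term in eligible:
            _, f = fit(current + [term])
            if not f.converged:
                skipped.add(term)
                candidates.remove(term)
                trace.add(term, "skipped_nonconverged")
                continue
            gain = f.loglik - current_fit.loglik
            if best is None or gain > best[1]:
                best = (term, gain, f)
        if best is None:
            break
        term, gain, f = best
        order += 1
        current.append(term)
        candidates.remove(term)
        current_fit = f
        trace.add(term, "added", add_order=order, loglik_gain=float(gain))

    # backward pruning
    while current:
        removable = [
            t for t in current if not any(t in _subterms(o) for o in current if o != t)
        ]
        worst = None
        for term in removable:
            reduced_terms = [t for t in current if t != term]
            _, fr = fit(reduced_terms)
            if not fr.converged:
                continue
            lrt = likelihood_ratio_test(current_fit, fr)
            if worst is None or lrt.pvalue > worst[1].pvalue:
                worst = (term, lrt, fr)
        if worst is None or worst[1].pvalue < alpha:
            break
        term, lrt, fr = worst
        current.remove(term)
        current_fit = fr
        trace.add(term, "pruned", lrt_p=float(lrt.pvalue))
    for term in current:
        trace.add(term, "kept")
    trace.final_terms = tuple(current)
    spec, final_fit = fit(current)
    if not final_fit.converged:
        raise SelectionError("final selected model failed to converge", trace)
    return spec, trace, final_fit


def _reference_row(data: pd.DataFrame, fit: ZipGlmmFit) -> dict:
    """Covariate settings that cancel in group differences (means/levels)."""
    row = {}
    for col in data.columns:
        v = data[col]
        if v.dtype.kind in "OUSb" or isinstance(v.dtype, pd.CategoricalDtype):
            row[col] = sorted(v.astype(str).unique())[0]
        else:
            row[col] = float(v.mean())
    return row


def marginal_means_contrasts(
    fit: ZipGlmmFit,
    data: pd.DataFrame,
    *,
    adjust: str = "bonferroni",
    group_scores: str = "moca_visit1",
) -> pd.DataFrame:
    """Normal-minus-abnormal marginal-means contrast per region pair x visit.

    Patients are grouped by their visit-1 MoCA against the clinical cutoff
    of 26; each group is represented by its median MoCA score at the
    contrasted visit, and the contrast is the difference of the model's
    linear predictors (log expected count) between those representative
    scores.  Delta-method standard errors use the fixed-effect covariance;
    p-values are adjusted (Holm or Bonferroni) over the estimable
    pair x visit family.

    ``data`` must be the design frame the model was fit on (used for the
    pair/visit levels, group medians, and nuisance-covariate means).
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    if adjust not in ("holm", "bonferroni"):
        raise ValueError("adjust must be 'holm' or 'bonferroni'")
    from .glmm import build_design

    subj = data.drop_duplicates("subject")
    groups = pd.Series(moca_group(subj[group_scores].to_numpy()), index=subj["subject"].to_numpy())
    ref = _reference_row(data.drop(columns=["count"]), fit)
    pairs = sorted(data["pair"].unique())
    visits = sorted(data["visit"].astype(str).unique())
    p = len(fit.beta)
    cov_beta = fit.cov_params[:p, :p]
    rows = []
    for pair in pairs:
        for visit in visits:
            reps = {}
            for g in ("normal", "abnormal"):
                members = groups.index[groups == g]
                sub = data[
                    (data["subject"].isin(members)) & (data["visit"].astype(str) == visit)
                ]
                reps[g] = float(sub["moca"].median()) if len(sub) else np.nan
            estimable = np.isfinite(reps["normal"]) and np.isfinite(reps["abnormal"])
            if estimable:
                grid = pd.DataFrame(
                    [
                        {**ref, "pair": pair, "visit": visit, "moca": reps["normal"]},
                        {**ref, "pair": pair, "visit": visit, "moca": reps["abnormal"]},
                    ]
                )
                X, names, _ = build_design(grid, fit.spec.fixed_terms, fit.levels)
                d = X[0] - X[1]
                est = float(d @ fit.beta.to_numpy())
                se = float(np.sqrt(max(d @ cov_beta @ d, 0.0)))
            else:
                est = se = np.nan
            src, dst = pair.split(" -> ")
            rows.append(
                {
                    "src_region": src,
                    "dst_region": dst,
                    "visit": visit,
                    "estimate": est,
                    "se": se,
                    "estimable": estimable,
                }
            )
    out = pd.DataFrame(rows)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["z_ratio"] = out["estimate"] / out["se"]
    out["p_raw"] = 2 * stats.norm.sf(np.abs(out["z_ratio"]))
    ok = out["estimable"] & np.isfinite(out["p_raw"]) & (out["se"] > 0)
    out["p_adj"] = np.nan
    if ok.any():
        out.loc[ok, "p_adj"] = multipletests(out.loc[ok, "p_raw"], method=adjust)[1]
    out["method"] = adjust
    return out


def visitwise_increase_test(
    counts: RegionPairCounts,
    *,
    alpha: float = 0.05,
    n_nodes: int = 7,
) -> pd.DataFrame:
    """Per-pair test of increased connectivity at visit 2.

    Fits ``count ~ visit + (1|subject)`` per ordered pair (visit coded
    0/1 for visit 1/2), Bonferroni-adjusts the two-sided Wald p-values
    over the pairs, and flags significant increases (positive visit
    coefficient).  Subjects lacking either visit are excluded with a
    warning.
    """
    idx = counts.index
    by_subj = idx.groupby("subject")["visit"].nunique()
    incomplete = by_subj.index[by_subj < 2]
    keep = ~idx["subject"].isin(incomplete).to_numpy()
    if len(incomplete):
        warnings.warn(
            f"excluding {len(incomplete)} subject(s) without both visits: "
            f"{list(incomplete)[:5]}"
        )
    idx = idx.loc[keep].reset_index(drop=True)
    mats = counts.counts[keep]
    order = np.argsort(idx["subject"].to_numpy(), kind="stable")
    idx = idx.iloc[order].reset_index(drop=True)
    mats = mats[order]
    groups = pd.factorize(idx["subject"])[0]
    R = len(counts.regions)
    Y = mats.reshape(len(idx), R * R).T.astype(float)
    X = np.column_stack([np.ones(len(idx)), (idx["visit"] == 2).to_numpy(float)])
    res = fit_zip_batch(Y, X, groups, n_nodes=n_nodes, compute_se=True)
    est = res["beta"][:, 1]
    se = res["se_beta"][:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = est / se
    p_raw = 2 * stats.norm.sf(np.abs(z))
    n_pairs = R * R
    p_adj = np.minimum(p_raw * n_pairs, 1.0)
    rows = []
    k = 0
    for i in range(R):
        for j in range(R):
            rows.append(
                {
                    "src_region": counts.regions[i],
                    "dst_region": counts.regions[j],
                    "estimate": est[k],
                    "se": se[k],
                    "converged": bool(res["converged"][k]),
                    "p_raw": p_raw[k],
                    "p_bonferroni": p_adj[k],
                    "significant_increase": bool(
                        res["converged"][k] and p_adj[k] < alpha and est[k] > 0
                    ),
                }
            )
            k += 1
    return pd.DataFrame(rows)
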