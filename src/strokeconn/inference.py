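"""Whole-network inference: per-pair models, enhancement, permutation test.

For every ordered region pair a ZIP random-intercept model
``count ~ covariate + (1|subject)`` is fit across trials; the covariate
coefficients form a signed network that is enhanced with nbs-TFCE and
tested with a two-sided max-statistic permutation test: the subject-level
covariate is shuffled across subjects (all trials of a subject keep the
shuffled value), every pair model is refit per shuffle, and each observed
cell's enhanced score is compared with the permutation distribution of the
family-wise maximum enhanced score over both signs and all cells.

Permutation refits run in the single-node Laplace fast mode and are
vectorized across permutations and cells in one batched optimizer call;
observed-data fits use full adaptive quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glmm import fit_zip_batch
from .links import RegionPairCounts
from .tfce import DEFAULT_E, DEFAULT_H, DEFAULT_N_STEPS, EnhancedNetwork, tfce_enhance

__all__ = [
    "CoefficientNetwork",
    "PermutationResult",
    "WHOLE_BRAIN_ANALYSES",
    "subject_covariate",
    "fit_link_models",
    "max_stat_permutation",
]

#: The whole-brain model specifications: analysis name -> (visit whose
#: connectivity is modelled, subject covariate driving the fixed effect).
#: ``None`` visit uses trials from both visits.
WHOLE_BRAIN_ANALYSES = {
    "moca1": (1, "moca_visit1"),
    "moca2": (2, "moca_visit2"),
    "moca_change": (1, "moca_change"),
    "moca2_from_visit1": (1, "moca_visit2"),
    "lesion_hemisphere": (None, "lesion_hemisphere"),
}


@dataclass
class CoefficientNetwork:
    """Fixed-effect coefficient of interest per ordered region pair."""

    coef: np.ndarray
    se: np.ndarray
    converged: np.ndarray
    regions: list[str]
    covariate: str

    def masked_coef(self) -> np.ndarray:
        """Coefficients with non-converged cells zeroed (excluded)."""
        return np.where(self.converged, np.nan_to_num(self.coef), 0.0)


@dataclass
class PermutationResult:
    """Observed enhancement, null maxima, and per-cell Monte-Carlo p-values."""

    observed: CoefficientNetwork
    enhanced: EnhancedNetwork
    null_max: np.ndarray
    pvalues: np.ndarray
    n_perm: int
    seed: int
    n_nonconverged: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        R = len(self.observed.regions)
        score = self.enhanced.positive - self.enhanced.negative
        for i in range(R):
            for j in range(R):
                rows.append(
                    {
                        "src_region": self.observed.regions[i],
                        "dst_region": self.observed.regions[j],
                        "coef": self.observed.coef[i, j],
                        "se": self.observed.se[i, j],
                        "converged": bool(self.observed.converged[i, j]),
                        "enhanced": score[i, j],
                        "pvalue": self.pvalues[i, j],
                    }
                )
        return pd.DataFrame(rows)


def subject_covariate(cohort: pd.DataFrame, name: str) -> pd.Series:
    """Numeric per-subject covariate (derived columns supported).

    ``moca_change`` is visit-2 minus visit-1 MoCA; ``lesion_hemisphere``
    is coded 0 = left, 1 = right.
    """
    if name == "moca_change":
        vals = (cohort["moca_visit2"] - cohort["moca_visit1"]).astype(float)
    elif name == "lesion_hemisphere":
        vals = cohort["lesion_hemisphere"].eq("right").astype(float)
    else:
        if name not in cohort.columns:
            raise KeyError(f"covariate {name!r} not in cohort table")
        vals = cohort[name].astype(float)
    return pd.Series(vals.to_numpy(), index=cohort["subject"].to_numpy(), name=name)


def _trial_design(counts: RegionPairCounts, cohort: pd.DataFrame, covariate: str, visit):
    """Sorted trial layout: response matrix (cells, N), covariate, groups."""
    keep = np.ones(len(counts.index), dtype=bool)
    if visit is not None:
        keep = counts.index["visit"].to_numpy() == visit
    idx = counts.index.loc[keep].reset_index(drop=True)
    mats = counts.counts[keep]
    missing = set(idx["subject"]) - set(cohort["subject"])
    if missing:
        raise KeyError(f"subjects in counts missing from cohort: {sorted(missing)}")
    order = np.argsort(idx["subject"].to_numpy(), kind="stable")
    idx = idx.iloc[order].reset_index(drop=True)
    mats = mats[order]
    groups = pd.factorize(idx["subject"])[0]
    cov = subject_covariate(cohort, covariate)
    x = idx["subject"].map(cov).to_numpy(dtype=float)
    R = len(counts.regions)
    Y = mats.reshape(len(idx), R * R).T.astype(float)  # (cells, N)
    return Y, x, groups, idx


def analyzable_cells(Y: np.ndarray, min_nonzero: int) -> np.ndarray:
    """Cells with enough nonzero trials to identify a slope.

    The rule depends on the counts only (never on the covariate), so the
    same cells enter the observed and every permuted analysis and
    exchangeability under the null is preserved.
    """
    return (Y > 0).sum(axis=1) >= min_nonzero


def fit_link_models(
    counts: RegionPairCounts,
    cohort: pd.DataFrame,
    covariate: str,
    visit: int | None = None,
    *,
    n_nodes: int = 15,
    zero_inflation: bool = True,
    min_nonzero: int = 5,
    return_raw: bool = False,
) -> CoefficientNetwork:
    """Fit ``count ~ covariate + (1|subject)`` to every ordered region pair.

    Returns the covariate coefficient (log-rate scale) per cell with its
    standard error and convergence flag.  Cells with fewer than
    ``min_nonzero`` nonzero trial counts are excluded (unidentifiable
    slope) and flagged non-converged, as are cells whose optimizer failed.
    A constant covariate yields a fully non-converged network (degenerate
    design) rather than an error.
    """
    Y, x, groups, _ = _trial_design(counts, cohort, covariate, visit)
    R = len(counts.regions)
    C = R * R
    coef = np.full(C, np.nan)
    se = np.full(C, np.nan)
    conv = np.zeros(C, dtype=bool)
    keep = analyzable_cells(Y, min_nonzero)
    res = None
    if np.ptp(x) > 0 and keep.any():
        X = np.column_stack([np.ones_like(x), x - x.mean()])
        res = fit_zip_batch(
            Y[keep], X, groups, n_nodes=n_nodes,
            zero_inflation=zero_inflation, compute_se=True,
        )
        coef[keep] = res["beta"][:, 1]
        se[keep] = res["se_beta"][:, 1]
        conv[keep] = res["converged"]
    network = CoefficientNetwork(
        coef=coef.reshape(R, R),
        se=se.reshape(R, R),
        converged=conv.reshape(R, R),
        regions=list(counts.regions),
        covariate=covariate,
    )
    if return_raw:
        return network, {"keep": keep, "batch": res}
    return network


def max_stat_permutation(
    counts: RegionPairCounts,
    cohort: pd.DataFrame,
    covariate: str,
    visit: int | None = None,
    *,
    n_perm: int = 1000,
    E: float = DEFAULT_E,
    H: float = DEFAULT_H,
    n_steps: int = DEFAULT_N_STEPS,
    seed: int = 0,
    n_nodes_observed: int = 15,
    perm_mode: str = "laplace",
    zero_inflation: bool = True,
    min_nonzero: int = 5,
    chunk_cells: int = 4_000_000,
) -> PermutationResult:
    """Two-sided max-statistic permutation test of an enhanced network.

    The test statistic is computed through one fully symmetric path: the
    unshuffled covariate ordering and the ``n_perm`` subject-level
    shuffles are refit with the same batched fast-mode (Laplace by
    default) optimizer, identical warm starts, and identical nbs-TFCE
    enhancement, so observed and null scores are exchangeable under the
    null by construction.  The family-wise maximum enhanced score per
    shuffle forms the null; cell p-values use the smoothed estimator
    ``(1 + #{null max >= score}) / (1 + n_perm)`` and are therefore never
    zero.  The reported coefficient table (``result.observed``) comes
    from full-quadrature fits.  Deterministic given ``seed``; shuffles
    are pre-drawn so results do not depend on the execution chunking.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Y, x, groups, idx = _trial_design(counts, cohort, covariate, visit)
    if len(np.unique(x)) < 2:
        raise ValueError("covariate has fewer than 2 distinct values; invalid test")
    R = len(counts.regions)
    C = R * R
    N = Y.shape[1]

    observed, raw = fit_link_models(
        counts, cohort, covariate, visit,
        n_nodes=n_nodes_observed, zero_inflation=zero_inflation,
        min_nonzero=min_nonzero, return_raw=True,
    )

    # shuffle index 0 is the identity: the observed statistic runs through
    # exactly the same code path as every null shuffle
    subj_of_obs = groups
    n_subj = subj_of_obs.max() + 1
    first_obs = np.r_[0, 1 + np.nonzero(np.diff(subj_of_obs))[0]]
    x_subj = x[first_obs]
    rng = np.random.default_rng(seed)
    perms = np.vstack(
        [np.arange(n_subj)[None, :]]
        + [rng.permutation(n_subj)[None, :] for _ in range(n_perm)]
    )

    perm_nodes = 1 if perm_mode == "laplace" else n_nodes_observed
    n_total = n_perm + 1
    max_scores = np.empty(n_total)
    n_nonconv = np.empty(n_total, dtype=int)
    keep = raw["keep"]
    Yk = Y[keep]
    Ck = int(keep.sum())
    enhanced = None
    obs_score = np.zeros((R, R))
    chunk = max(1, int(chunk_cells // (max(Ck, 1) * N)))
    for lo in range(0, n_total, chunk):
        hi = min(lo + chunk, n_total)
        P = hi - lo
        coefs = np.zeros((P, C))
        conv = np.ones((P, C), dtype=bool)
        if Ck:
            x_perm = x_subj[perms[lo:hi]][:, subj_of_obs]  # (P, N)
            x_perm = x_perm - x_perm.mean(axis=1, keepdims=True)
            Xb = np.empty((P, N, 2))
            Xb[:, :, 0] = 1.0
            Xb[:, :, 1] = x_perm
            Xb = np.repeat(Xb, Ck, axis=0)  # (P*Ck, N, 2)
            Yb = np.broadcast_to(Yk, (P, Ck, N)).reshape(P * Ck, N)
            res = fit_zip_batch(
                Yb, Xb, groups, n_nodes=perm_nodes,
                zero_inflation=zero_inflation, compute_se=False,
                final_readapt=False,
            )
            ck = res["beta"][:, 1].reshape(P, Ck)
            cv = res["converged"].reshape(P, Ck)
            coefs[:, keep] = np.where(cv, np.nan_to_num(ck), 0.0)
            conv[:, keep] = cv
        for k in range(P):
            en = tfce_enhance(coefs[k].reshape(R, R), E, H, n_steps)
            max_scores[lo + k] = en.max_score()
            n_nonconv[lo + k] = int((~conv[k]).sum())
            if lo + k == 0:
                enhanced = en
                obs_score = en.positive + en.negative  # disjoint supports

    null_max = max_scores[1:]
    pvals = (1.0 + (null_max[:, None, None] >= obs_score[None]).sum(axis=0)) / (
        1.0 + n_perm
    )
    return PermutationResult(
        observed=observed,
        enhanced=enhanced,
        null_max=null_max,
        pvalues=pvals,
        n_perm=n_perm,
        seed=seed,
        n_nonconverged=n_nonconv[1:],
    )
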