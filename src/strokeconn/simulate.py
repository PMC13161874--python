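"""Synthetic cohort and link-list generator.

Emulates the output of an upstream directed-connectivity detector run on a
two-visit minor-stroke cohort: subject covariates with realistic marginals,
and trial-level directed patch-to-patch link lists whose region-pair counts
follow a zero-inflated Poisson with a per-subject baseline intercept, a
global between-visit increase, and optional planted covariate-linked
network effects.

Counts are generated in *ipsilesional-aligned* space (left = lesioned
hemisphere); subjects with a right-hemisphere lesion then have their patch
ids reflected so the emitted table looks anatomical, exactly undoing what
:func:`strokeconn.links.mirror_for_lesion` applies downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import PatchAtlas
from .links import LINK_COLUMNS

__all__ = [
    "EffectSpec",
    "SimulationConfig",
    "generate_cohort",
    "simulate_patch_links",
    "ground_truth_network",
]


@dataclass(frozen=True)
class EffectSpec:
    """A planted covariate-linked effect on a set of directed region pairs.

    ``slope`` is the change in log expected link count per unit of the
    (cohort-mean-centred) driving covariate; ``visit`` restricts the effect
    to one visit (``None`` applies it to both).  Region labels follow the
    aligned convention, e.g. ``("R.fpc", "R.dorsolateral_prefrontal")``.
    """

    target_pairs: frozenset
    covariate: str
    slope: float
    visit: int | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope):
            raise ValueError("slope must be finite")
        object.__setattr__(self, "target_pairs", frozenset(self.target_pairs))


@dataclass
class SimulationConfig:
    """Generator settings.

    Defaults give sparse 22x22 matrices with a visible zero excess: baseline
    expected count exp(-1.9) ~ 0.15 links per ordered pair and trial
    (~70 links per trial across 484 pairs), 20% structural zeros, subject
    intercept SD 0.3, and a +0.5 log-rate global increase at visit 2.
    """

    n_subjects: int = 49
    n_trials_per_visit: int = 2
    baseline_log_rate: float = -1.9
    subject_sd: float = 0.3
    zero_inflation: float = 0.2
    visit2_log_increase: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials_per_visit < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.zero_inflation < 1.0:
            raise ValueError("zero_inflation must be in [0, 1)")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be >= 0")


def generate_cohort(
    n_subjects: int,
    seed: int,
    *,
    age_mean: float = 62.4,
    age_sd: float = 13.9,
    prop_male: float = 0.57,
    prop_black: float = 0.39,
    education_mean: float = 13.7,
    education_sd: float = 2.4,
    prop_left_lesion: float = 0.47,
    moca_mean: float = 24.0,
    moca_sd: float = 3.0,
    moca_gain_mean: float = 1.5,
    moca_gain_sd: float = 2.0,
) -> pd.DataFrame:
    """Draw a synthetic stroke cohort with the study's covariate marginals.

    Visit-1 MoCA is a discretised normal truncated to [0, 30]; visit-2 MoCA
    adds a rounded normal improvement increment (positive mean: most
    patients improve between visits) and is re-truncated.  Default marginals
    match the cohort description (mean age 62.4 y (SD 13.9), 57% male, 39%
    Black, 13.7 y education, 47% left-hemisphere lesions).

    Returns a DataFrame with columns ``subject``, ``moca_visit1``,
    ``moca_visit2``, ``lesion_hemisphere``, ``age``, ``sex``, ``race``,
    ``education_years``.  Deterministic given ``seed``.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    rng = np.random.default_rng(seed)
    moca1 = np.clip(np.rint(rng.normal(moca_mean, moca_sd, n_subjects)), 0, 30)
    gain = np.rint(rng.normal(moca_gain_mean, moca_gain_sd, n_subjects))
    moca2 = np.clip(moca1 + gain, 0, 30)
    return pd.DataFrame(
        {
            "subject": [f"S{i:03d}" for i in range(n_subjects)],
            "moca_visit1": moca1.astype(int),
            "moca_visit2": moca2.astype(int),
            "lesion_hemisphere": np.where(
                rng.random(n_subjects) < prop_left_lesion, "left", "right"
            ),
            "age": rng.normal(age_mean, age_sd, n_subjects).round(1),
            "sex": np.where(rng.random(n_subjects) < prop_male, "male", "female"),
            "race": np.where(rng.random(n_subjects) < prop_black, "black", "other"),
            "education_years": np.clip(
                np.rint(rng.normal(education_mean, education_sd, n_subjects)), 6, 22
            ).astype(int),
        }
    )


def _effect_matrix(
    effects, regions: list[str], visit: int
) -> tuple[np.ndarray, list[str]]:
    """Per-pair planted slope matrices, one per distinct covariate."""
    pos = {r: i for i, r in enumerate(regions)}
    covs: list[str] = []
    mats: list[np.ndarray] = []
    for eff in effects:
        if eff.visit is not None and eff.visit != visit:
            continue
        for a, b in eff.target_pairs:
            if a not in pos or b not in pos:
                raise ValueError(f"effect references unknown region {(a, b)!r}")
        if eff.covariate not in covs:
            covs.append(eff.covariate)
            mats.append(np.zeros((len(regions), len(regions))))
        m = mats[covs.index(eff.covariate)]
        for a, b in eff.target_pairs:
            m[pos[a], pos[b]] += eff.slope
    return (np.stack(mats) if mats else np.zeros((0, len(regions), len(regions)))), covs


def simulate_region_counts(
    cohort: pd.DataFrame,
    config: SimulationConfig,
    effects=(),
    regions=None,
) -> "RegionPairCounts":
    """Simulate per-trial region-pair count matrices directly.

    For every subject x visit x trial and ordered region pair the count is
    a zero-inflated Poisson draw with

    ``log lam = baseline + u_subject + visit2_shift * [visit == 2]
    + sum_k slope_k * (covariate_k - cohort mean)``.

    ``regions`` defaults to the 22 atlas regions but any label list works
    (scaled-down studies use small pseudo-region sets).  Labels follow the
    ipsilesional-aligned convention, so no mirroring is needed downstream.
    Deterministic given ``config.seed``.
    """
    from .links import RegionPairCounts

    if regions is None:
        from .atlas import default_atlas

        regions = default_atlas().regions
    regions = list(regions)
    R = len(regions)
    rng = np.random.default_rng(config.seed)
    for v in (1, 2):
        _effect_matrix(effects, regions, v)

    cov_values: dict[str, np.ndarray] = {}

    def covariate(name: str) -> np.ndarray:
        if name not in cov_values:
            from .inference import subject_covariate

            vals = subject_covariate(cohort, name).to_numpy()
            cov_values[name] = vals - vals.mean()
        return cov_values[name]

    u = rng.normal(0.0, config.subject_sd, len(cohort))
    index_rows = []
    mats = []
    for s_idx, subj in enumerate(cohort.itertuples(index=False)):
        for visit in (1, 2):
            slopes, covs = _effect_matrix(effects, regions, visit)
            eta = np.full((R, R), config.baseline_log_rate + u[s_idx])
            if visit == 2:
                eta += config.visit2_log_increase
            for m, cov in zip(slopes, covs):
                eta = eta + m * covariate(cov)[s_idx]
            lam = np.exp(eta)
            for trial in range(1, config.n_trials_per_visit + 1):
                counts = rng.poisson(lam)
                if config.zero_inflation > 0:
                    counts[rng.random((R, R)) < config.zero_inflation] = 0
                index_rows.append((subj.subject, visit, trial))
                mats.append(counts)
    index = pd.DataFrame(index_rows, columns=["subject", "visit", "trial"])
    return RegionPairCounts(index=index, counts=np.stack(mats), regions=regions)


def simulate_patch_links(
    cohort: pd.DataFrame,
    config: SimulationConfig,
    effects=(),
    atlas: PatchAtlas | None = None,
) -> pd.DataFrame:
    """Simulate a trial-level directed link table.

    Region-pair counts are drawn by :func:`simulate_region_counts`; each
    link is then assigned uniformly at random to a patch pair within its
    region pair, and right-lesion subjects' patch ids are reflected into
    anatomical space (undone downstream by ``mirror_for_lesion``).
    Deterministic given ``config.seed``.
    """
    if atlas is None:
        from .atlas import default_atlas

        atlas = default_atlas()
    regions = atlas.regions
    counts = simulate_region_counts(cohort, config, effects, regions)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    region_patches = {r: atlas.patches_in_region(r) for r in regions}
    lesion = dict(zip(cohort["subject"], cohort["lesion_hemisphere"]))
    flip = {"L": "R", "R": "L"}
    rows: list[tuple] = []
    for k, key in enumerate(counts.index.itertuples(index=False)):
        mirror = lesion[key.subject] == "right"
        mat = counts.counts[k]
        for i, j in zip(*np.nonzero(mat)):
            c = mat[i, j]
            src = rng.choice(region_patches[regions[i]], size=c)
            dst = rng.choice(region_patches[regions[j]], size=c)
            for sp, dp in zip(src, dst):
                if mirror:
                    sp = flip[sp[0]] + sp[1:]
                    dp = flip[dp[0]] + dp[1:]
                rows.append((key.subject, key.visit, key.trial, sp, dp))
    return pd.DataFrame(rows, columns=LINK_COLUMNS)


def ground_truth_network(effects, regions: list[str]) -> np.ndarray:
    """Signed matrix of planted slopes over ordered region pairs.

    Entry (i, j) is the sum of the slopes of every effect targeting the
    pair (regions[i], regions[j]); zero elsewhere.  Visit restrictions are
    ignored here; use per-visit slices via :class:`EffectSpec.visit` when
    needed.
    """
    pos = {r: i for i, r in enumerate(regions)}
    out = np.zeros((len(regions), len(regions)))
    for eff in effects:
        for a, b in eff.target_pairs:
            out[pos[a], pos[b]] += eff.slope
    return out
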