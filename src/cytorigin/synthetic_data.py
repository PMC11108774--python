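"""Seeded generators for every input the pipeline needs.

Four families: cytology-like raster tiles (for tiling/QC/self-supervised
paths), feature bags with planted witness instances and covariate-class
dependence (for the MIL heads), multi-rater label matrices with tunable
agreement, and survival cohorts with known hazards.  All generators are pure
functions of (config, seed).

The feature-bag model is deliberately statistical rather than photorealistic:
positive bags mix "witness" vectors (Gaussian with a class-specific mean
shift) into a background cloud, mirroring the assumption that a malignant
smear contains at least one patch with tumor cells while a benign smear
contains none.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .bagio import CATEGORIES, ClinicalCovariates, OriginLabel
from .errors import ConfigurationError, ParameterError

MALIGNANT = tuple(c for c in CATEGORIES if c != "benign")

# Class-conditional covariate model, echoing the qualitative site-origin
# association of effusion cytology: digestive tumors seed ascites,
# respiratory tumors seed hydrothorax, breast/gynecologic tumors skew female.
DEFAULT_SITE_ASCITES_P = {
    "digestive": 0.80, "female_reproductive": 0.60, "respiratory": 0.15,
    "blood_lymphatic": 0.40, "benign": 0.40,
}
DEFAULT_FEMALE_P = {
    "digestive": 0.45, "female_reproductive": 0.98, "respiratory": 0.45,
    "blood_lymphatic": 0.50, "benign": 0.55,
}
DEFAULT_AGE_MEAN = {
    "digestive": 61.0, "female_reproductive": 55.0, "respiratory": 63.0,
    "blood_lymphatic": 52.0, "benign": 58.0,
}


@dataclass
class BagSimConfig:
    """Conditions for the synthetic feature-bag cohort."""

    n_cases: int = 200
    d: int = 64
    min_patches: int = 8
    max_patches: int = 24
    witness_rate: float = 0.6          # fraction of discriminative instances in positive bags
    class_shift: float = 2.5           # witness mean shift in feature space
    class_probs: Optional[Dict[str, float]] = None   # default: balanced
    site_ascites_p: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SITE_ASCITES_P))
    female_p: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FEMALE_P))
    age_mean: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AGE_MEAN))
    age_sd: float = 10.0
    uncertainty_fraction: float = 0.0  # cases emitted without a label
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.witness_rate <= 1.0):
            raise ConfigurationError("witness rate must be in (0, 1] for malignant classes")
        if self.class_probs is None:
            self.class_probs = {c: 1.0 / len(CATEGORIES) for c in CATEGORIES}


@dataclass
class SimulatedBags:
    manifest: pd.DataFrame
    bags: Dict[str, np.ndarray]
    labels: Dict[str, OriginLabel]
    covariates: Dict[str, ClinicalCovariates]
    witness_masks: Dict[str, np.ndarray]

    def split_ids(self, split: str):
        return list(self.manifest.loc[self.manifest["split"] == split, "case_id"])


# --------------------------------------------------------------------- tiles
_TILE_STYLE = {
    # (n_blobs, blob_radius, cluster_spread, RGB cell color)
    "digestive": (26, 14, 60.0, (120, 60, 140)),
    "female_reproductive": (18, 10, 25.0, (190, 70, 150)),
    "respiratory": (40, 6, 18.0, (60, 80, 170)),
    "blood_lymphatic": (70, 4, 90.0, (40, 40, 120)),
    "benign": (8, 9, 80.0, (170, 150, 190)),
}


def gen_tiles(class_id: str, count: int, seed: int, size: int = 224) -> np.ndarray:
    """Procedural class-specific textures as (count, size, size, 3) uint8 tiles.

    Blob size, clustering and chromatic profile differ by class, mimicking the
    morphological cues (papillary, wreath-like and compact cell clusters) that
    distinguish tumor origins on smears.  Deterministic per seed.
    """
    if class_id not in _TILE_STYLE:
        raise ParameterError(f"unknown class id {class_id!r}")
    rng = np.random.default_rng(seed)
    n_blobs, radius, spread, color = _TILE_STYLE[class_id]
    color = np.array(color, dtype=np.float64)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    tiles = np.empty((count, size, size, 3), dtype=np.uint8)
    for t in range(count):
        img = np.full((size, size, 3), 235.0)
        img += rng.normal(0, 4, size=(size, size, 3))
        n_clusters = max(1, n_blobs // 8)
        centers = rng.uniform(0, size, size=(n_clusters, 2))
        for _ in range(n_blobs):
            cy, cx = centers[rng.integers(n_clusters)] + rng.normal(0, spread, 2)
            r = radius * rng.uniform(0.6, 1.4)
            mask = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * r**2)))
            shade = rng.uniform(0.7, 1.0)
            img += mask[..., None] * (color * shade - img) * 0.9
        tiles[t] = np.clip(img, 0, 255).astype(np.uint8)
    return tiles


# --------------------------------------------------------------- feature bags
def _class_mean(cls: str, d: int, shift: float) -> np.ndarray:
    mu = np.zeros(d)
    idx = MALIGNANT.index(cls)
    block = max(1, d // (len(MALIGNANT) + 1))
    mu[idx * block:(idx + 1) * block] = shift / np.sqrt(block)
    return mu


def gen_feature_bags(config: BagSimConfig) -> SimulatedBags:
    """Cohort of labeled feature bags with planted class signal.

    Positive bags mix witness vectors (background + class mean shift, at
    least one per bag) with background N(0, I) vectors; benign bags are
    background-only.  Covariates follow the configured class-conditional
    model.  Emits a stratified 60/20/20 train/val/test split.
    """
    for cls in MALIGNANT:
        if config.witness_rate <= 0:
            raise ConfigurationError("witness rate must be positive for malignant classes")
    rng = np.random.default_rng(config.seed)
    classes = list(config.class_probs)
    probs = np.array([config.class_probs[c] for c in classes], dtype=float)
    probs = probs / probs.sum()

    rows, bags, labels, covs, masks = [], {}, {}, {}, {}
    n_uncertain = int(round(config.uncertainty_fraction * config.n_cases))
    for i in range(config.n_cases):
        cid = f"case_{i:04d}"
        cls = classes[rng.choice(len(classes), p=probs)]
        k = int(rng.integers(config.min_patches, config.max_patches + 1))
        X = rng.normal(size=(k, config.d))
        witness = np.zeros(k, dtype=bool)
        if cls != "benign":
            witness = rng.random(k) < config.witness_rate
            if not witness.any():
                witness[rng.integers(k)] = True
            X[witness] += _class_mean(cls, config.d, config.class_shift)
        age = int(np.clip(round(rng.normal(config.age_mean[cls], config.age_sd)), 18, 90))
        sex = "female" if rng.random() < config.female_p[cls] else "male"
        site = "ascites" if rng.random() < config.site_ascites_p[cls] else "hydrothorax"
        uncertain = i < n_uncertain
        label = (OriginLabel(fine="unknown", certainty="uncertainty") if uncertain
                 else OriginLabel(fine=cls, coarse=cls, certainty="high"))
        bags[cid] = X
        labels[cid] = label
        covs[cid] = ClinicalCovariates(age=age, sex=sex, site=site)
        masks[cid] = witness
        rows.append({"case_id": cid, "image_path": "", "age": age, "sex": sex,
                     "site": site, "fine_label": label.fine,
                     "coarse_label": label.coarse, "certainty": label.certainty,
                     "split": "train"})

    manifest = pd.DataFrame(rows)
    # stratified split by (label or 'uncertainty')
    strat = manifest["coarse_label"].fillna("uncertainty")
    for _, idx in manifest.groupby(strat, sort=True).groups.items():
        idx = list(idx)
        perm = rng.permutation(len(idx))
        n_tr = int(round(0.6 * len(idx)))
        n_va = int(round(0.2 * len(idx)))
        for j, p in enumerate(perm):
            split = "train" if j < n_tr else ("val" if j < n_tr + n_va else "test")
            manifest.loc[idx[p], "split"] = split
    return SimulatedBags(manifest=manifest, bags=bags, labels=labels,
                         covariates=covs, witness_masks=masks)


# --------------------------------------------------------------- rater matrix
def gen_rater_matrix(n_cases: int, r: int, rho: float, seed: int,
                     n_categories: int = len(CATEGORIES),
                     marginal: Optional[np.ndarray] = None) -> np.ndarray:
    """Cases x categories counts of rater assignments with tunable agreement.

    Each case has a latent label; each of the ``r`` raters reports it with
    probability ``rho`` and otherwise draws from the marginal.  ``rho`` tunes
    Fleiss' kappa monotonically (rho=1 gives kappa=1).
    """
    if r < 2:
        raise ParameterError("at least 2 raters are required")
    if not (0.0 <= rho <= 1.0):
        raise ParameterError("rho must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if marginal is None:
        marginal = np.full(n_categories, 1.0 / n_categories)
    marginal = np.asarray(marginal, dtype=float)
    marginal = marginal / marginal.sum()
    latent = rng.choice(n_categories, size=n_cases, p=marginal)
    counts = np.zeros((n_cases, n_categories), dtype=int)
    for i in range(n_cases):
        for _ in range(r):
            if rng.random() < rho:
                cat = latent[i]
            else:
                cat = rng.choice(n_categories, p=marginal)
            counts[i, cat] += 1
    return counts


# ------------------------------------------------------------ survival cohort
def _uniform_censor_bound(lam: float, rate: float) -> float:
    """Upper bound b of U(0, b) censoring achieving P(C < T) = rate for T ~ Exp(lam)."""
    # P(C < T) = (1 - exp(-lam*b)) / (lam*b) for C ~ U(0, b), T ~ Exp(lam)
    def f(b):
        return (1.0 - np.exp(-lam * b)) / (lam * b) - rate
    return brentq(f, 1e-9, 1e6)


def gen_survival_cohort(n: int, hr: float, baseline_median: float,
                        censoring_rate: float, seed: int,
                        with_covariates: bool = True) -> pd.DataFrame:
    """Two balanced groups with exponential event times and uniform censoring.

    The reference group has hazard ln2/median; the alternative group hazard
    ``hr`` times that.  Columns follow the survival-analysis schema: ``time``
    (months), ``event`` (1=death), ``group`` (0=reference, 1=alternative),
    plus optional uninformative covariates for multivariate fits.
    """
    if n < 2:
        raise ParameterError("n must be at least 2")
    if hr <= 0:
        raise ParameterError("hazard ratio must be positive")
    if not (0.0 <= censoring_rate < 1.0):
        raise ParameterError("censoring rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    lam_ref = np.log(2.0) / baseline_median
    lam_alt = hr * lam_ref
    group = np.zeros(n, dtype=int)
    group[n // 2:] = 1
    lam = np.where(group == 0, lam_ref, lam_alt)
    t_event = rng.exponential(1.0 / lam)
    if censoring_rate > 0:
        bounds = np.where(group == 0,
                          _uniform_censor_bound(lam_ref, censoring_rate),
                          _uniform_censor_bound(lam_alt, censoring_rate))
        c = rng.uniform(0, bounds)
    else:
        c = np.full(n, np.inf)
    time = np.minimum(t_event, c)
    event = (t_event <= c).astype(int)
    df = pd.DataFrame({"time": time, "event": event, "group": group})
    if with_covariates:
        df["age"] = np.clip(rng.normal(60, 12, n).round(), 18, 90)
        df["sex_male"] = rng.integers(0, 2, n)
        df["met_sites"] = rng.poisson(1.5, n) + 1
    return df


# -------------------------------------------------- synthetic CUP stand-in
# Marginal composition of the treatment-concordance cohort the analysis
# targets (restricted-access clinical data; this generator is a synthetic
# stand-in, not the deposited table).
CUP_COMPOSITION = {
    "n": 391,
    "concordant": {"n": 276, "deaths": 102, "median_os": 27.0},
    "discordant": {"n": 115, "deaths": 61, "median_os": 17.0},
    "treated": {  # 310 patients on palliative chemotherapy / targeted drugs
        "concordant": {"n": 214, "PR": 75, "SD": 91, "PD": 48},
        "discordant": {"n": 96, "PR": 14, "SD": 29, "PD": 53},
    },
    # the admission window spans ~3.4 years to the census date; per-group
    # follow-up horizons are calibrated so the model's natural death
    # probability equals the reported death fraction (both land near 40 mo)
    "prediction_mix": {"female_reproductive": 197, "respiratory": 122,
                       "digestive": 55, "blood_lymphatic": 17},
}


def synthetic_cup_cohort(seed: int = 0) -> pd.DataFrame:
    """Synthetic stand-in for the 391-patient CUP treatment-concordance cohort.

    Event times are exponential with the group's reported median survival;
    censoring arises from uniform staggered admission over the follow-up
    window.  Group sizes, death counts and RECIST response counts are fixed
    exactly at the reported composition (per-subject times are drawn
    conditionally on the death/censoring indicator, which preserves the
    generating hazards).  Everything else (ages, sexes, metastatic sites) is
    synthetic noise.  This table exercises the survival module; it is not the
    deposited clinical data.
    """
    rng = np.random.default_rng(seed)
    rows = []
    pred_pool = []
    for cat, cnt in CUP_COMPOSITION["prediction_mix"].items():
        pred_pool += [cat] * cnt
    pred_pool = list(rng.permutation(pred_pool))

    for grp in ("concordant", "discordant"):
        comp = CUP_COMPOSITION[grp]
        lam = np.log(2.0) / comp["median_os"]
        death_frac = comp["deaths"] / comp["n"]
        # horizon b of the uniform admission window such that P(T <= C) with
        # C ~ U(0, b) equals the group's death fraction
        horizon = brentq(lambda b: 1.0 - (1.0 - np.exp(-lam * b)) / (lam * b) - death_frac,
                         1e-6, 1e4)
        treated = CUP_COMPOSITION["treated"][grp]
        responses = (["PR"] * treated["PR"] + ["SD"] * treated["SD"] +
                     ["PD"] * treated["PD"] +
                     [None] * (comp["n"] - treated["n"]))
        responses = list(rng.permutation(np.array(responses, dtype=object)))
        flags = np.zeros(comp["n"], dtype=int)
        flags[:comp["deaths"]] = 1
        flags = rng.permutation(flags)
        for i in range(comp["n"]):
            # rejection-sample (T, C) conditional on the death indicator
            while True:
                t = rng.exponential(1.0 / lam)
                c = rng.uniform(0.0, horizon)
                died = t <= c
                if died == bool(flags[i]):
                    break
            resp = responses[i]
            rows.append({
                "time": t if flags[i] else c,
                "event": int(flags[i]),
                "concordance": grp,
                "response": resp,
                "treatment": "chemo_targeted" if resp is not None else "surgery_supportive",
                "age": int(np.clip(round(rng.normal(62, 11)), 28, 88)),
                "sex": "male" if rng.random() < 0.5 else "female",
                "prediction": pred_pool.pop(),
                "source": "hydrothorax" if rng.random() < 0.6 else "ascites",
                "met_sites": int(rng.poisson(1.4)) + 1,
                "karnofsky_admission": float(np.clip(round(rng.normal(62, 15) / 10) * 10, 10, 100)),
            })
    df = pd.DataFrame(rows)
    # post-treatment functional score: concordant patients fare better on average
    shift = np.where(df["concordance"] == "concordant", 52.1, 41.8)
    df["karnofsky_3_6m"] = np.clip((rng.normal(shift, 19.0)/ 10).round() * 10, 10, 100)
    df["patient_id"] = [f"cup_{i:03d}" for i in range(len(df))]
    return df
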