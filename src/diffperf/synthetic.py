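"""Synthetic cohort generator.

Emulates the statistical structure of a two-group small-vessel-disease
imaging study: a 74-case / 39-control cohort with 308 atlas-wise
features (4 diffusion metrics x 48 white-matter labels + CBF x 116
gray-matter labels), a configurable set of planted case-control mean
differences, exchangeable within-modality background correlation, and
cognitive scores constructed so that chosen (feature, test) pairs have
a prescribed partial correlation (given sex/age/education) within the
case group.

The default configuration plants the 13 discriminative features and the
7 significant feature-cognition associations that such a study reports,
using the published group means as the planted means.  Group SDs are
not published; the default common SD is set per feature so the planted
effect size is Cohen's d = 0.8.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
import numpy as np

from .schema import (
    Cohort,
    FeatureName,
    SubjectRecord,
    build_feature_index,
    gm_labels,
    wm_labels,
)
import pandas as pd

__all__ = [
    "PlantedEffect",
    "PlantedAssociation",
    "GroupScore",
    "SyntheticConfig",
    "ConfigError",
    "default_paper_config",
    "generate_cohort",
]


class ConfigError(ValueError):
    """Invalid synthetic-cohort configuration."""


@dataclass(frozen=True)
class PlantedEffect:
    """A feature with different group means and a common SD."""

    feature: str  # feature column name
    control_mean: float
    case_mean: float
    sd: float

    @property
    def cohens_d(self) -> float:
        return abs(self.case_mean - self.control_mean) / self.sd


@dataclass(frozen=True)
class PlantedAssociation:
    """Target partial correlation (given sex/age/education), case group."""

    feature: str
    test: str
    r: float


@dataclass(frozen=True)
class GroupScore:
    """Marginal mean/SD of a cognitive test per group."""

    test: str
    case_mean: float
    case_sd: float
    control_mean: float
    control_sd: float


#: baseline mean and SD per metric for non-planted features; diffusivity
#: metrics are on the conventional 1e-4 mm^2/s scale, CBF in mL/100g/min
BACKGROUND_LEVELS = {
    "FA": (0.42, 0.035),
    "MD": (8.0, 0.5),
    "AD": (12.5, 0.7),
    "RD": (6.0, 0.5),
    "CBF": (45.0, 8.0),
}

#: cognitive score distributions of the emulated study population
DEFAULT_SCORES = (
    GroupScore("MoCA", 21.72, 3.43, 26.33, 1.23),
    GroupScore("MMSE", 27.17, 1.98, 28.49, 1.23),
    GroupScore("TMT_A", 99.18, 50.60, 59.46, 15.10),
    GroupScore("TMT_B", 225.38, 87.38, 150.83, 38.41),
    GroupScore("Stroop_CT", 126.40, 56.94, 79.26, 15.36),
    GroupScore("VFT", 13.01, 4.00, 16.12, 3.63),
)

#: the discriminative features such a study identifies, with published
#: group means (CBF in mL/100g/min; FA unitless; AD on the 1e-4 scale)
PAPER_EFFECTS: tuple[tuple[str, float, float], ...] = (
    ("perfusion__CBF__Rolandic_Oper_R", 49.215, 55.617),
    ("perfusion__CBF__Supp_Motor_Area_R", 41.087, 48.511),
    ("perfusion__CBF__Frontal_Sup_Medial_R", 37.611, 40.417),
    ("perfusion__CBF__ParaHippocampal_L", 45.680, 50.681),
    ("perfusion__CBF__ParaHippocampal_R", 44.219, 50.527),
    ("perfusion__CBF__Caudate_R", 34.338, 35.348),
    ("perfusion__CBF__Temporal_Sup_L", 51.629, 56.769),
    ("perfusion__CBF__Cerebelum_4_5_R", 41.420, 43.792),
    ("diffusion__FA__right_anterior_corona_radiata", 0.316, 0.346),
    ("diffusion__AD__right_posterior_corona_radiata", 13.612, 13.125),
    ("diffusion__FA__left_external_capsule", 0.328, 0.350),
    ("diffusion__FA__right_superior_longitudinal_fasciculus", 0.369, 0.380),
    ("diffusion__FA__left_uncinate_fasciculus", 0.336, 0.357),
)

#: the significant case-group feature-cognition partial correlations
PAPER_ASSOCIATIONS: tuple[tuple[str, str, float], ...] = (
    ("diffusion__AD__right_posterior_corona_radiata", "TMT_A", 0.339),
    ("diffusion__FA__left_external_capsule", "TMT_A", -0.361),
    ("diffusion__FA__right_anterior_corona_radiata", "TMT_B", -0.404),
    ("diffusion__AD__right_posterior_corona_radiata", "TMT_B", 0.391),
    ("diffusion__FA__left_external_capsule", "TMT_B", -0.359),
    ("diffusion__FA__right_superior_longitudinal_fasciculus", "TMT_B", -0.368),
    ("diffusion__FA__right_anterior_corona_radiata", "VFT", 0.377),
)


@dataclass
class SyntheticConfig:
    """Everything :func:`generate_cohort` needs; serializable to JSON."""

    n_case: int = 74
    n_control: int = 39
    n_wm_labels: int = 48
    n_gm_labels: int = 116
    planted_effects: tuple[PlantedEffect, ...] = ()
    planted_associations: tuple[PlantedAssociation, ...] = ()
    scores: tuple[GroupScore, ...] = DEFAULT_SCORES
    #: exchangeable correlation between any two features of one modality
    background_rho: float = 0.3
    male_fraction: float = 0.77
    age_case: tuple[float, float] = (65.97, 6.84)
    age_control: tuple[float, float] = (63.44, 7.04)
    age_bounds: tuple[float, float] = (50.0, 85.0)
    education: tuple[float, float] = (10.5, 2.6)
    education_bounds: tuple[float, float] = (6.0, 22.0)
    #: variance share of each covariate in every cognitive score
    covariate_share: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ConfigError("group sizes must be >= 2")
        if not 0 <= self.background_rho < 1:
            raise ConfigError("background_rho must be in [0, 1)")
        for e in self.planted_effects:
            if e.sd <= 0:
                raise ConfigError(f"planted SD must be positive: {e.feature}")
        for a in self.planted_associations:
            if not abs(a.r) < 1:
                raise ConfigError(f"|target r| must be < 1: {a.feature}")
        tests = {s.test for s in self.scores}
        for a in self.planted_associations:
            if a.test not in tests:
                raise ConfigError(f"association targets unknown test {a.test}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        d["planted_effects"] = tuple(
            PlantedEffect(**e) for e in d.get("planted_effects", ())
        )
        d["planted_associations"] = tuple(
            PlantedAssociation(**a) for a in d.get("planted_associations", ())
        )
        d["scores"] = tuple(GroupScore(**s) for s in d.get("scores", ()))
        for k in ("age_case", "age_control", "age_bounds", "education",
                  "education_bounds"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def default_paper_config(effect_d: float = 0.8, seed: int = 0) -> SyntheticConfig:
    """The study-emulating default: 74/39 cohort, 13 planted features
    at Cohen's d = ``effect_d``, 7 planted case-group associations."""
    effects = tuple(
        PlantedEffect(
            feature=f,
            control_mean=ctrl,
            case_mean=case,
            sd=abs(case - ctrl) / effect_d,
        )
        for f, case, ctrl in PAPER_EFFECTS
    )
    assocs = tuple(
        PlantedAssociation(feature=f, test=t, r=r)
        for f, t, r in PAPER_ASSOCIATIONS
    )
    return SyntheticConfig(
        planted_effects=effects, planted_associations=assocs, seed=seed
    )


def _truncnorm(rng, mean, sd, lo, hi, size):
    """Normal draws redrawn into [lo, hi] (simple rejection)."""
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, bad.sum())
    return np.clip(out, lo, hi)


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Draw one cohort. Deterministic given ``config.seed``.

    Features: x_ij = mu_j(group) + sd_j * (sqrt(rho) f_i^mod +
    sqrt(1-rho) e_ij), giving every pair of same-modality features
    correlation rho. Cognitive scores in the case group are linear in
    the standardized planted features with coefficients a = R^{-1} r
    (R the feature correlation matrix restricted to that test's planted
    features), plus covariate terms and noise scaled so the population
    partial correlation of each planted pair equals its target.
    """
    config.validate()
    index = build_feature_index(
        wm_labels()[: config.n_wm_labels], gm_labels()[: config.n_gm_labels]
    )
    if config.n_wm_labels > 48 or config.n_gm_labels > 116:
        raise ConfigError("label lists ship 48 WM / 116 GM names")
    columns = [f.column for f in index]
    col_pos = {c: i for i, c in enumerate(columns)}
    for e in config.planted_effects:
        if e.feature not in col_pos:
            raise ConfigError(f"planted feature not in index: {e.feature}")
    for a in config.planted_associations:
        if a.feature not in col_pos:
            raise ConfigError(f"association feature not in index: {a.feature}")

    rng = np.random.default_rng(config.seed)
    n = config.n_case + config.n_control
    diagnosis = np.r_[np.ones(config.n_case, int), np.zeros(config.n_control, int)]

    # demographics
    sex = (rng.random(n) < config.male_fraction).astype(int)
    age = np.where(
        diagnosis == 1,
        _truncnorm(rng, *config.age_case, *config.age_bounds, n),
        _truncnorm(rng, *config.age_control, *config.age_bounds, n),
    )
    edu = _truncnorm(rng, *config.education, *config.education_bounds, n)

    # Feature matrix. Background features of one modality share a
    # latent factor (pairwise correlation rho); planted features carry
    # independent noise so the discriminative ground truth is exactly
    # the planted set -- were the factor shared, background features
    # would hold genuine conditional (noise-canceling) signal and the
    # notion of a false positive would collapse.
    p = len(index)
    rho = config.background_rho
    modality = np.array([f.modality == "perfusion" for f in index])
    planted_pos = {col_pos[e.feature]: e for e in config.planted_effects}
    is_planted = np.zeros(p, dtype=bool)
    is_planted[list(planted_pos)] = True
    factor = rng.normal(size=(n, 2))  # one latent factor per modality
    eps = rng.normal(size=(n, p))
    z = np.where(
        is_planted[None, :],
        eps,
        np.sqrt(rho) * factor[:, modality.astype(int)]
        + np.sqrt(1 - rho) * eps,
    )

    means = np.empty(p)
    sds = np.empty(p)
    for i, f in enumerate(index):
        means[i], sds[i] = BACKGROUND_LEVELS[f.metric]
    for j, e in planted_pos.items():
        sds[j] = e.sd
    X = means[None, :] + sds[None, :] * z
    for j, e in planted_pos.items():
        mu = np.where(diagnosis == 1, e.case_mean, e.control_mean)
        X[:, j] = mu + e.sd * z[:, j]

    # cognitive scores
    case = diagnosis == 1
    cov = np.c_[sex, age, edu].astype(float)
    cov_z = np.empty_like(cov)
    scores_by_test = {s.test: s for s in config.scores}
    assoc_by_test: dict[str, list[PlantedAssociation]] = {}
    for a in config.planted_associations:
        assoc_by_test.setdefault(a.test, []).append(a)

    cog = {}
    share = config.covariate_share
    for s in config.scores:
        vals = np.empty(n)
        for grp, mean_, sd_ in (
            (case, s.case_mean, s.case_sd),
            (~case, s.control_mean, s.control_sd),
        ):
            m = int(grp.sum())
            # standardized covariates within the group
            czm = cov[grp]
            czm = (czm - czm.mean(0)) / np.where(czm.std(0) > 0, czm.std(0), 1)
            cov_part = np.sqrt(share) * czm.sum(axis=1)
            # variance left after the covariates; the partial correlation
            # conditions the covariates away, so targets are hit inside
            # this share
            v = 1.0 - 3 * share
            feat_part = np.zeros(m)
            feat_share = 0.0
            targets = assoc_by_test.get(s.test, []) if grp is case else []
            if targets:
                jj = [col_pos[a.feature] for a in targets]
                r_t = np.array([a.r for a in targets])
                # population correlation of the targeted features:
                # planted-effect features are mutually independent,
                # background pairs share rho within modality
                k = len(jj)
                same = np.equal.outer(modality[jj], modality[jj])
                bg = ~is_planted[jj]
                both_bg = np.outer(bg, bg)
                R = np.where(same & both_bg, rho, 0.0) * (
                    1 - np.eye(k)
                ) + np.eye(k)
                sol = np.linalg.solve(R, r_t)
                r_Rinv_r = float(r_t @ sol)
                if r_Rinv_r >= 1:
                    raise ConfigError(
                        f"targets for {s.test} are jointly infeasible "
                        f"(r'R^-1 r = {r_Rinv_r:.3f} >= 1)"
                    )
                a_coef = np.sqrt(v) * sol
                zg = z[grp][:, jj]  # standardized feature deviations
                feat_part = zg @ a_coef
                feat_share = v * r_Rinv_r
            noise = rng.normal(size=m)
            std_score = feat_part + cov_part + np.sqrt(v - feat_share) * noise
            vals[grp] = mean_ + sd_ * std_score
        cog[s.test] = vals

    width = len(str(n))
    subjects = []
    for i in range(n):
        subjects.append(
            SubjectRecord(
                subject_id=f"S{i + 1:0{width}d}",
                diagnosis=int(diagnosis[i]),
                sex=int(sex[i]),
                age=float(age[i]),
                education=float(edu[i]),
                cognitive_scores={t: float(cog[t][i]) for t in cog},
            )
        )
    table = pd.DataFrame(X, index=[s.subject_id for s in subjects],
                         columns=columns)
    table.index.name = "subject_id"
    return Cohort(subjects, table)
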