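"""Synthetic cohorts with known ground-truth variance structure.

The generator emulates an aging neuroimaging cohort: ~500 participants
aged 36-100, a fluid-cognition composite that declines with age, and
~18 named feature sets of heterogeneous dimensionality (region-level
"direct" sets and wide "connectivity" sets destined for PCA reduction).

Generative model (all latents standard normal, mutually independent
unless stated):

    z          standardized chronological age (age ~ Uniform(age_range))
    B_age      brain-aging latent  = sqrt(g)*z + sqrt(1-g)*eta
    A_k        per-set aging latent
               = sqrt(q_k)*B_age + sqrt(rho_k)*B_cog + sqrt(1-q_k-rho_k)*eta_k
    B_cog      brain-cognition latent, independent of age
    cognition  (standardized) = -sqrt(s_a)*z + sqrt(s_b)*B_cog + noise

Each feature column loads on exactly one of A_k or B_cog (plus an
additive sex shift and idiosyncratic noise). The overlap share rho_k
lets a set's aging signal carry cognition-relevant variance that age
itself does not: an age model built on such a set predicts age less
well, yet its predicted age retains unique information about
cognition beyond chronological age.

Because columns within a group are exchangeable, the population
best-linear-predictor of any target from a set reduces to the two
group means, so every designed R-squared is available exactly from a
2x2 covariance solve (see ``ground_truth_r2``). For a single group
with per-column share a and no overlap this reduces to the familiar

    kappa(m, a) = m*a / (1 + (m-1)*a)
    R2(age | set k features) = g * q_k * kappa(m_age_k, a_k)

The age-cognition association is generated negative by convention,
mirroring the decline of fluid cognition across the adult lifespan.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "FeatureSetSpec",
    "CohortSpec",
    "GroundTruth",
    "FeatureSetCollection",
    "generate_cohort",
    "ground_truth_r2",
    "study_spec",
    "demo_spec",
    "write_cohort",
    "load_cohort",
]

Kind = Literal["direct", "connectivity"]

#: categories used to resolve stacked-model membership
CATEGORIES = ("task_contrast", "task_fc", "rest_fc", "smri")


@dataclass(frozen=True)
class FeatureSetSpec:
    """One named feature set and its designed variance shares.

    Parameters
    ----------
    name : str
        Unique identifier, e.g. ``"cortical_thickness"``.
    n_features : int
        Number of columns generated for this set.
    kind : {"direct", "connectivity"}
        Connectivity sets are wide matrices that the prediction pipeline
        reduces by PCA before modelling; direct sets are used as-is.
    category : str
        One of ``task_contrast, task_fc, rest_fc, smri``; used to resolve
        which stacked models a set belongs to.
    age_signal_share : float
        Per-column variance share carried by the set's aging latent.
    brain_signal_share : float
        Per-column variance share carried by the brain-cognition latent
        (on the columns allocated to it).
    age_latent_fidelity : float
        Squared correlation q_k between this set's aging latent and the
        global brain-aging latent; controls how well the set can predict
        age and lets different sets have different ceilings.
    age_cog_overlap : float
        Share rho_k of the set's aging latent carried by the
        brain-cognition latent; nonzero values make the set's aging
        signal informative about cognition beyond chronological age.
    """

    name: str
    n_features: int
    kind: Kind = "direct"
    category: str = "smri"
    age_signal_share: float = 0.25
    brain_signal_share: float = 0.10
    age_latent_fidelity: float = 0.8
    age_cog_overlap: float = 0.0

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError(f"{self.name}: n_features must be >= 1")
        if self.kind not in ("direct", "connectivity"):
            raise ValueError(f"{self.name}: kind must be direct|connectivity")
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.name}: category must be one of {CATEGORIES}")
        for fname in ("age_signal_share", "brain_signal_share",
                      "age_latent_fidelity", "age_cog_overlap"):
            v = getattr(self, fname)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.name}: {fname}={v} outside [0, 1]")
        if self.age_latent_fidelity + self.age_cog_overlap > 1.0 + 1e-12:
            raise ValueError(
                f"{self.name}: age_latent_fidelity + age_cog_overlap exceeds 1"
            )

    @property
    def n_age_columns(self) -> int:
        if self.age_signal_share == 0:
            return 0
        if self.brain_signal_share == 0:
            return self.n_features
        return (self.n_features + 1) // 2

    @property
    def n_cog_columns(self) -> int:
        return self.n_features - self.n_age_columns


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort and its feature sets."""

    n_participants: int = 504
    age_range: tuple[float, float] = (36.0, 100.0)
    female_fraction: float = 293 / 504
    feature_sets: tuple[FeatureSetSpec, ...] = ()
    cognition_age_share: float = 0.32
    cognition_brain_share: float = 0.15
    sex_effect_size: float = 0.3
    brain_aging_strength: float = 0.85
    cognition_mean: float = 100.0
    cognition_sd: float = 15.0
    noise_free: bool = False
    recode_90_plus: bool = False

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must satisfy min < max")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction outside [0, 1]")
        for fname in ("cognition_age_share", "cognition_brain_share", "brain_aging_strength"):
            v = getattr(self, fname)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{fname}={v} outside [0, 1]")
        if self.cognition_age_share + self.cognition_brain_share > 1.0 + 1e-12:
            raise ValueError(
                "cognition_age_share + cognition_brain_share exceeds 1 "
                f"({self.cognition_age_share} + {self.cognition_brain_share})"
            )
        names = [s.name for s in self.feature_sets]
        if len(names) != len(set(names)):
            raise ValueError("feature set names must be unique")

    @property
    def n_feature_sets(self) -> int:
        return len(self.feature_sets)


@dataclass
class FeatureSetCollection:
    """Named participant x feature matrices plus their kind/category tags."""

    tables: dict[str, pd.DataFrame]
    kinds: dict[str, Kind]
    categories: dict[str, str]

    def __getitem__(self, name: str) -> pd.DataFrame:
        return self.tables[name]

    @property
    def names(self) -> list[str]:
        return list(self.tables)


@dataclass
class GroundTruth:
    """Closed-form population R-squared values implied by a CohortSpec.

    Feature-set values are defined after removal of the additive sex
    term (the prediction pipeline residualises sex from the features
    before modelling, and sex is generated independent of age).
    """

    expected_r2_age_cognition: float
    expected_r2_features_age: dict[str, float]
    expected_r2_features_cognition: dict[str, float]
    latent_loadings: dict[str, np.ndarray]


def _kappa(m: int, a: float) -> float:
    """Population R2 of a latent recovered from m equi-loading columns."""
    if m == 0 or a == 0.0:
        return 0.0
    return m * a / (1.0 + (m - 1) * a)


def _set_r2(fs: FeatureSetSpec, spec: CohortSpec) -> tuple[float, float]:
    """Population R2 of age and cognition given one set's features.

    Columns within a group are exchangeable, so the best linear
    predictor depends on the features only through the two group means
    (age-group and cognition-group); the R2 follows from their 2x2
    covariance with the target.
    """
    a, b = fs.age_signal_share, fs.brain_signal_share
    q, rho = fs.age_latent_fidelity, fs.age_cog_overlap
    g = spec.brain_aging_strength
    s_a, s_b = spec.cognition_age_share, spec.cognition_brain_share
    idio = 0.0 if spec.noise_free else 1.0
    var_cog = s_a + s_b + (0.0 if spec.noise_free else 1.0 - s_a - s_b)

    rows = []  # (variance of group mean, cov with z, cov with cog_std)
    if fs.n_age_columns > 0 and a > 0.0:
        var = a + idio * (1.0 - a) / fs.n_age_columns
        cov_z = np.sqrt(a * q * g)
        cov_c = np.sqrt(a) * (-np.sqrt(q * g * s_a) + np.sqrt(rho * s_b))
        rows.append((var, cov_z, cov_c, np.sqrt(a)))
    if fs.n_cog_columns > 0 and b > 0.0:
        var = b + idio * (1.0 - b) / fs.n_cog_columns
        cov_z = 0.0
        cov_c = np.sqrt(b * s_b)
        rows.append((var, cov_z, cov_c, np.sqrt(b)))
    if not rows:
        return 0.0, 0.0
    k = len(rows)
    s = np.zeros((k, k))
    for i in range(k):
        s[i, i] = rows[i][0]
    if k == 2:
        # both group means share B_cog: cov = sqrt(a*rho)*sqrt(b)
        s[0, 1] = s[1, 0] = np.sqrt(a * rho * b)
    c_z = np.array([r[1] for r in rows])
    c_c = np.array([r[2] for r in rows])
    sinv = np.linalg.inv(s)
    r2_age = float(c_z @ sinv @ c_z)
    r2_cog = float(c_c @ sinv @ c_c) / var_cog if var_cog > 0 else 0.0
    return r2_age, r2_cog


def ground_truth_r2(spec: CohortSpec) -> GroundTruth:
    """Closed-form ground truth for every designed relationship in *spec*."""
    s_a, s_b = spec.cognition_age_share, spec.cognition_brain_share
    resid = 0.0 if spec.noise_free else 1.0 - s_a - s_b
    var_cog = s_a + s_b + resid
    r2_age_cog = s_a / var_cog if var_cog > 0 else 0.0

    r2_age: dict[str, float] = {}
    r2_cog: dict[str, float] = {}
    loadings: dict[str, np.ndarray] = {}
    for fs in spec.feature_sets:
        r2_age[fs.name], r2_cog[fs.name] = _set_r2(fs, spec)
        lo = np.zeros((fs.n_features, 2))
        lo[: fs.n_age_columns, 0] = np.sqrt(fs.age_signal_share)
        lo[fs.n_age_columns :, 1] = np.sqrt(fs.brain_signal_share)
        loadings[fs.name] = lo
    return GroundTruth(r2_age_cog, r2_age, r2_cog, loadings)


def generate_cohort(
    spec: CohortSpec, seed: int
) -> tuple[pd.DataFrame, FeatureSetCollection, GroundTruth]:
    """Draw a cohort, its feature sets, and the implied ground truth.

    Identical ``(spec, seed)`` reproduces identical output bit-wise.

    Returns
    -------
    cohort : DataFrame
        Columns ``participant_id, age_years, sex, fluid_cognition``
        (sex: 1 = female, 0 = male), indexed by participant_id.
    features : FeatureSetCollection
    truth : GroundTruth
    """
    rng = np.random.default_rng(seed)
    n = spec.n_participants
    lo, hi = spec.age_range

    age = rng.uniform(lo, hi, size=n)
    # standardize with population moments of Uniform(lo, hi) so the
    # variance shares are exact in expectation
    z_age = (age - (lo + hi) / 2.0) / np.sqrt((hi - lo) ** 2 / 12.0)

    n_female = int(round(spec.female_fraction * n))
    sex = np.zeros(n, dtype=int)
    sex[rng.permutation(n)[:n_female]] = 1

    g = spec.brain_aging_strength
    b_age = np.sqrt(g) * z_age + np.sqrt(1.0 - g) * rng.standard_normal(n)
    b_cog = rng.standard_normal(n)

    s_a, s_b = spec.cognition_age_share, spec.cognition_brain_share
    cog_std = -np.sqrt(s_a) * z_age + np.sqrt(s_b) * b_cog
    if not spec.noise_free:
        cog_std = cog_std + np.sqrt(1.0 - s_a - s_b) * rng.standard_normal(n)
    cognition = spec.cognition_mean + spec.cognition_sd * cog_std

    if spec.recode_90_plus:
        age = np.where(age >= 90.0, 100.0, age)

    ids = np.array([f"P{i:05d}" for i in range(n)])
    cohort = pd.DataFrame(
        {
            "participant_id": ids,
            "age_years": age,
            "sex": sex,
            "fluid_cognition": cognition,
        }
    ).set_index("participant_id", drop=False)

    tables: dict[str, pd.DataFrame] = {}
    kinds: dict[str, Kind] = {}
    categories: dict[str, str] = {}
    for fs in spec.feature_sets:
        q, rho = fs.age_latent_fidelity, fs.age_cog_overlap
        a_latent = (
            np.sqrt(q) * b_age
            + np.sqrt(rho) * b_cog
            + np.sqrt(1.0 - q - rho) * rng.standard_normal(n)
        )
        m, ma = fs.n_features, fs.n_age_columns
        x = np.empty((n, m))
        x[:, :ma] = np.sqrt(fs.age_signal_share) * a_latent[:, None]
        x[:, ma:] = np.sqrt(fs.brain_signal_share) * b_cog[:, None]
        if not spec.noise_free:
            noise_sd = np.empty(m)
            noise_sd[:ma] = np.sqrt(1.0 - fs.age_signal_share)
            noise_sd[ma:] = np.sqrt(1.0 - fs.brain_signal_share)
            x += noise_sd[None, :] * rng.standard_normal((n, m))
        x += spec.sex_effect_size * sex[:, None]
        cols = [f"{fs.name}_f{j:05d}" for j in range(m)]
        tables[fs.name] = pd.DataFrame(x, index=cohort.index, columns=cols)
        kinds[fs.name] = fs.kind
        categories[fs.name] = fs.category

    return cohort, FeatureSetCollection(tables, kinds, categories), ground_truth_r2(spec)


# ---------------------------------------------------------------------------
# canned specifications

_CONTRAST_SETS = [
    # (name, fidelity q_k, overlap rho_k): q spread so age-prediction
    # ceilings vary across sets; one memory-task set carries aging
    # signal that overlaps cognition beyond age
    ("facename_encode", 0.55, 0.0),
    ("facename_recall", 0.50, 0.0),
    ("facename_distractor", 0.30, 0.20),
    ("facename_encode_vs_distractor", 0.40, 0.0),
    ("facename_recall_vs_distractor", 0.38, 0.0),
    ("facename_encode_vs_recall", 0.30, 0.0),
    ("carit_nogo", 0.50, 0.0),
    ("carit_go", 0.55, 0.0),
    ("carit_nogo_vs_go", 0.35, 0.0),
    ("vismotor", 0.45, 0.0),
]

_SMRI_SETS = [
    ("cortical_thickness", 148, 0.90),
    ("cortical_surface_area", 148, 0.70),
    ("subcortical_volume", 19, 0.60),
    ("total_brain_volume", 5, 0.55),
]


def study_spec(
    n_participants: int = 504,
    contrast_dim: int = 379,
    connectivity_dim: int = 71_631,
    **overrides,
) -> CohortSpec:
    """The 18-set cohort layout the package emulates by default.

    Ten task-contrast region-level sets, three task-FC and one rest-FC
    connectivity sets (wide pairwise matrices, PCA-reduced downstream),
    and four structural sets. ``connectivity_dim`` defaults to the
    off-diagonal count of a 379-region parcellation; pass a smaller
    value for desk-scale runs.
    """
    sets = [
        FeatureSetSpec(name, contrast_dim, "direct", "task_contrast",
                       age_signal_share=0.20, brain_signal_share=0.08,
                       age_latent_fidelity=q, age_cog_overlap=rho)
        for name, q, rho in _CONTRAST_SETS
    ]
    for name in ("facename_fc", "carit_fc", "vismotor_fc"):
        sets.append(
            FeatureSetSpec(name, connectivity_dim, "connectivity", "task_fc",
                           age_signal_share=0.04, brain_signal_share=0.02,
                           age_latent_fidelity=0.70)
        )
    sets.append(
        FeatureSetSpec("rest_fc", connectivity_dim, "connectivity", "rest_fc",
                       age_signal_share=0.04, brain_signal_share=0.02,
                       age_latent_fidelity=0.85)
    )
    for name, dim, q in _SMRI_SETS:
        sets.append(
            FeatureSetSpec(name, dim, "direct", "smri",
                           age_signal_share=0.30, brain_signal_share=0.12,
                           age_latent_fidelity=q)
        )
    return CohortSpec(n_participants=n_participants, feature_sets=tuple(sets), **overrides)


def demo_spec(n_participants: int = 300, **overrides) -> CohortSpec:
    """A four-set scaled-down cohort for quick end-to-end runs."""
    sets = (
        FeatureSetSpec("cortical_thickness", 40, "direct", "smri",
                       age_signal_share=0.30, brain_signal_share=0.12,
                       age_latent_fidelity=0.90),
        FeatureSetSpec("subcortical_volume", 19, "direct", "smri",
                       age_signal_share=0.30, brain_signal_share=0.12,
                       age_latent_fidelity=0.60),
        FeatureSetSpec("vismotor", 40, "direct", "task_contrast",
                       age_signal_share=0.20, brain_signal_share=0.08,
                       age_latent_fidelity=0.45),
        FeatureSetSpec("rest_fc", 120, "connectivity", "rest_fc",
                       age_signal_share=0.05, brain_signal_share=0.03,
                       age_latent_fidelity=0.85),
    )
    return CohortSpec(n_participants=n_participants, feature_sets=sets, **overrides)


# ---------------------------------------------------------------------------
# on-disk layout: phenotype CSV + one feature CSV per set + JSON manifest

def write_cohort(
    out_dir: str | Path,
    cohort: pd.DataFrame,
    features: FeatureSetCollection,
    truth: GroundTruth | None = None,
) -> Path:
    """Write phenotype CSV, per-set feature CSVs, manifest and ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(out / "phenotypes.csv", index=False)
    manifest = {"phenotypes": "phenotypes.csv", "feature_sets": []}
    for name in features.names:
        fname = f"features_{name}.csv"
        features[name].to_csv(out / fname, index=True, index_label="participant_id")
        manifest["feature_sets"].append(
            {
                "name": name,
                "path": fname,
                "kind": features.kinds[name],
                "category": features.categories[name],
            }
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if truth is not None:
        payload = {
            "expected_r2_age_cognition": truth.expected_r2_age_cognition,
            "expected_r2_features_age": truth.expected_r2_features_age,
            "expected_r2_features_cognition": truth.expected_r2_features_cognition,
        }
        (out / "ground_truth.json").write_text(json.dumps(payload, indent=2))
    return out / "manifest.json"


def load_cohort(manifest_path: str | Path) -> tuple[pd.DataFrame, FeatureSetCollection]:
    """Read a phenotype table and feature sets described by a manifest.

    This is also the adapter for user-supplied data: any tables in the
    documented layout load the same way as generated ones.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    cohort = pd.read_csv(base / manifest["phenotypes"], dtype={"participant_id": str})
    required = {"participant_id", "age_years", "sex", "fluid_cognition"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    cohort = cohort.set_index("participant_id", drop=False)
    tables, kinds, categories = {}, {}, {}
    for entry in manifest["feature_sets"]:
        df = pd.read_csv(base / entry["path"], dtype={"participant_id": str})
        df = df.set_index("participant_id")
        if not df.index.equals(cohort.index):
            missing_ids = cohort.index.difference(df.index)
            raise ValueError(
                f"feature set {entry['name']!r} does not cover the cohort "
                f"(e.g. missing {list(missing_ids[:3])})"
            )
        tables[entry["name"]] = df
        kinds[entry["name"]] = entry["kind"]
        categories[entry["name"]] = entry.get("category", "smri")
    return cohort, FeatureSetCollection(tables, kinds, categories)
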