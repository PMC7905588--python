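"""Synthetic physical-examination cohorts with planted statistical structure.

The generator emulates the three study populations (healthy controls,
sub-health fatigue, disease fatigue) that the network and canonical
correlation analyses assume:

* binary symptom/index records whose co-occurrence is driven by latent
  syndrome factors through a noisy-OR mixing rule,
* H20 health-questionnaire scores drawn from truncated per-group
  distributions so the grouping rules can be exercised honestly,
* continuous tongue-colour and pulse-waveform parameter blocks with a
  planted first canonical correlation between them.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from fatiguenet.containers import BinaryCohortMatrix, Feature, TonguePulseTable

GROUPS = ("healthy", "subhealth", "disease")

#: The 14 tongue parameters: 12 colour-space values of the tongue body
#: (RGB, HSI, Lab, YCrCb) plus the two coating-area ratios.
TONGUE_PARAMS = [
    "TB-R", "TB-G", "TB-B", "TB-H", "TB-S", "TB-I",
    "TB-L", "TB-a", "TB-b", "TB-Y", "TB-Cr", "TB-Cb",
    "perAll", "perPart",
]

#: Base sphygmogram parameters: amplitudes h, timings t, widths w.
PULSE_BASE_PARAMS = ["h1", "h3", "h4", "h5", "t1", "t4", "t5", "t", "w1", "w2"]

#: Derived pulse ratios, computed from the generated base parameters.
PULSE_RATIOS = ["h4/h1", "h3/h1", "w2/t", "h1/t1"]

# Physiologic-looking location/scale pairs. Locations sit far from zero so
# the derived ratios are finite; exact values are configuration, not contract.
_TONGUE_SCALES = {
    "TB-R": (150.0, 12.0), "TB-G": (95.0, 9.0), "TB-B": (98.0, 9.0),
    "TB-H": (24.0, 4.0), "TB-S": (0.35, 0.05), "TB-I": (115.0, 10.0),
    "TB-L": (52.0, 5.0), "TB-a": (22.0, 3.5), "TB-b": (12.0, 3.0),
    "TB-Y": (112.0, 9.0), "TB-Cr": (152.0, 5.0), "TB-Cb": (112.0, 5.0),
    "perAll": (0.42, 0.08), "perPart": (0.72, 0.10),
}
_PULSE_SCALES = {
    "h1": (14.0, 1.2), "h3": (9.0, 0.9), "h4": (7.0, 0.8), "h5": (1.6, 0.2),
    "t1": (0.14, 0.010), "t4": (0.40, 0.025), "t5": (0.35, 0.025),
    "t": (0.85, 0.050), "w1": (0.22, 0.018), "w2": (0.16, 0.014),
}


@dataclass(frozen=True)
class LatentFactor:
    """A latent syndrome factor driving symptom/index co-occurrence.

    ``loadings`` maps feature codes to values in [0, 1]; ``activation`` maps
    group names to the probability that the factor is active in a subject of
    that group. When a factor is active its loadings raise the positivity
    probability of the loaded features through the noisy-OR rule
    ``p = 1 - (1 - baseline) * prod(1 - loading_f)``.
    """

    name: str
    loadings: dict[str, float]
    activation: dict[str, float]

    def __post_init__(self) -> None:
        for code, w in self.loadings.items():
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"loading for {code} must be in [0, 1], got {w}")
        for group, p in self.activation.items():
            if group not in GROUPS:
                raise ValueError(f"unknown group {group!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"activation for {group} must be in [0, 1], got {p}")


@dataclass
class CohortSpec:
    """Configuration for one synthetic three-group cohort."""

    n_healthy: int
    n_subhealth: int
    n_disease: int
    features: list[Feature]
    factors: list[LatentFactor] = field(default_factory=list)
    #: per-group (mean, sd, lower, upper) of the truncated-normal H20 score
    h20_params: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "healthy": (88.0, 6.0, 80.0, 100.0),
            "subhealth": (70.0, 5.5, 60.0, 79.0),
            "disease": (68.0, 12.0, 0.0, 100.0),
        }
    )
    #: per-group probability that the subject reports the fatigue chief complaint
    fatigue_prob: dict[str, float] = field(
        default_factory=lambda: {"healthy": 0.05, "subhealth": 1.0, "disease": 1.0}
    )
    #: optional disease subgroup labels, (name, proportion); proportions renormalized
    disease_subgroups: list[tuple[str, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for n in (self.n_healthy, self.n_subhealth, self.n_disease):
            if n < 0:
                raise ValueError("group sizes must be >= 0")
        for group, p in self.fatigue_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"fatigue probability for {group} must be in [0, 1]")
        for group, (mean, sd, lo, hi) in self.h20_params.items():
            if sd <= 0 or lo > hi:
                raise ValueError(f"invalid H20 parameters for {group}: {(mean, sd, lo, hi)}")
        codes = {f.code for f in self.features}
        for factor in self.factors:
            unknown = set(factor.loadings) - codes
            if unknown:
                raise ValueError(f"factor {factor.name!r} loads on unknown features {sorted(unknown)}")


@dataclass
class Cohort:
    """Output of :func:`gen_binary_cohort`."""

    matrix: BinaryCohortMatrix
    groups: pd.Series          # generative group label per subject
    h20: pd.Series             # H20 questionnaire score
    fatigue: pd.Series         # fatigue chief-complaint flag (bool)
    subgroups: pd.Series | None = None

    def to_frame(self) -> pd.DataFrame:
        """One row per subject: id, group, h20, fatigue, features..."""
        out = pd.DataFrame(
            {"group": self.groups, "h20": self.h20, "fatigue": self.fatigue.astype(int)},
            index=self.matrix.data.index,
        )
        if self.subgroups is not None:
            out["subgroup"] = self.subgroups
        return pd.concat([out, self.matrix.data], axis=1)


def gen_binary_cohort(spec: CohortSpec) -> Cohort:
    """Draw a synthetic binary cohort under the noisy-OR latent-factor model.

    For each subject, the factors active in their group are drawn
    independently; feature ``j`` is then positive with probability
    ``1 - (1 - baseline_j) * prod over active factors f of (1 - loading_fj)``.
    H20 scores come from the group's truncated normal distribution.
    """
    rng = np.random.default_rng(spec.seed)
    codes = [f.code for f in spec.features]
    base = np.array([f.prevalence for f in spec.features])
    n_feat = len(codes)

    sizes = {"healthy": spec.n_healthy, "subhealth": spec.n_subhealth, "disease": spec.n_disease}
    rows, groups, h20s, fatigue = [], [], [], []
    for group in GROUPS:
        n = sizes[group]
        if n == 0:
            continue
        # complement-probability matrix: start from 1 - baseline, multiply in
        # (1 - loading) for every active factor, then p = 1 - complement
        comp = np.tile(1.0 - base, (n, 1))
        for factor in spec.factors:
            active = rng.random(n) < factor.activation.get(group, 0.0)
            if not active.any():
                continue
            fac = np.ones(n_feat)
            for code, w in factor.loadings.items():
                fac[codes.index(code)] = 1.0 - w
            comp[active] *= fac
        rows.append((rng.random((n, n_feat)) < (1.0 - comp)).astype(np.int8))
        groups.extend([group] * n)

        mean, sd, lo, hi = spec.h20_params[group]
        a, b = (lo - mean) / sd, (hi - mean) / sd
        h20s.append(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng))
        fatigue.append(rng.random(n) < spec.fatigue_prob.get(group, 0.0))

    if rows:
        data = np.vstack(rows)
        h20_all = np.concatenate(h20s)
        fat_all = np.concatenate(fatigue)
    else:
        data = np.empty((0, n_feat), dtype=np.int8)
        h20_all = np.empty(0)
        fat_all = np.empty(0, dtype=bool)
    ids = [f"S{i:05d}" for i in range(len(groups))]
    matrix = BinaryCohortMatrix(pd.DataFrame(data, index=ids, columns=codes), list(spec.features))
    group_s = pd.Series(groups, index=ids, name="group")

    subgroup_s = None
    if spec.disease_subgroups:
        names = [n for n, _ in spec.disease_subgroups]
        props = np.array([p for _, p in spec.disease_subgroups], dtype=float)
        props = props / props.sum()
        sub = pd.Series("", index=ids, name="subgroup")
        mask = group_s == "disease"
        sub[mask] = rng.choice(names, size=int(mask.sum()), p=props)
        subgroup_s = sub

    return Cohort(
        matrix=matrix,
        groups=group_s,
        h20=pd.Series(h20_all, index=ids, name="h20"),
        fatigue=pd.Series(fat_all, index=ids, name="fatigue"),
        subgroups=subgroup_s,
    )


@dataclass
class TonguePulseSpec:
    """Configuration for one tongue/pulse block pair with planted correlation.

    A latent bivariate-normal pair (u, v) with correlation ``rho`` drives the
    two blocks: every tongue column mixes ``loading * u`` with independent
    noise of scale ``noise_sd`` (in standardized units), every pulse base
    column likewise with v, and the result is shifted onto a
    physiologic-looking scale. The derived pulse ratios (h4/h1, h3/h1, w2/t,
    h1/t1) are then computed from the generated base columns.
    """

    n_subjects: int
    rho: float
    tongue_loading: np.ndarray | None = None   # unit-norm over TONGUE_PARAMS
    pulse_loading: np.ndarray | None = None    # unit-norm over PULSE_BASE_PARAMS
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [0, 1], got {self.rho}")
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.tongue_loading is None:
            self.tongue_loading = _default_tongue_loading()
        if self.pulse_loading is None:
            self.pulse_loading = _default_pulse_loading()
        self.tongue_loading = _check_unit(np.asarray(self.tongue_loading, float),
                                          len(TONGUE_PARAMS), "tongue_loading")
        self.pulse_loading = _check_unit(np.asarray(self.pulse_loading, float),
                                         len(PULSE_BASE_PARAMS), "pulse_loading")


def _check_unit(v: np.ndarray, n: int, name: str) -> np.ndarray:
    if v.shape != (n,):
        raise ValueError(f"{name} must have length {n}, got shape {v.shape}")
    norm = float(np.linalg.norm(v))
    if abs(norm - 1.0) > 1e-8:
        raise ValueError(f"{name} must have unit Euclidean norm, got {norm:.6f}")
    return v


def _unit(values: list[float]) -> np.ndarray:
    v = np.asarray(values, float)
    return v / np.linalg.norm(v)


def _default_tongue_loading() -> np.ndarray:
    # Emphasis on Cb, b, H and the coating ratios, the colour channels that
    # carry most tongue-appearance contrast; signs mixed as in real loadings.
    raw = dict.fromkeys(TONGUE_PARAMS, 0.10)
    raw.update({"TB-Cb": -0.50, "TB-b": 0.50, "TB-H": 0.48, "TB-Cr": 0.35,
                "perAll": -0.35, "TB-a": 0.25, "TB-L": -0.20})
    return _unit([raw[p] for p in TONGUE_PARAMS])


def _default_pulse_loading() -> np.ndarray:
    # Main-wave amplitude h1 and the dicrotic parameters dominate.
    raw = dict.fromkeys(PULSE_BASE_PARAMS, 0.08)
    raw.update({"h1": 0.60, "h4": -0.45, "h3": -0.35, "t1": -0.30, "w2": 0.25, "t": 0.15})
    return _unit([raw[p] for p in PULSE_BASE_PARAMS])


def gen_tongue_pulse(spec: TonguePulseSpec) -> TonguePulseTable:
    """Generate a tongue/pulse table with first canonical correlation ≈ rho.

    With unit-norm loadings and per-column noise ``noise_sd`` the population
    first canonical correlation equals ``rho / (1 + noise_sd**2)`` (each
    block attenuates by ``sqrt(1/(1 + noise_sd**2))``); the default
    ``noise_sd = 0.1`` keeps the attenuation below 0.01.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    u = rng.standard_normal(n)
    if spec.rho >= 1.0:
        v = u.copy()
    else:
        v = spec.rho * u + np.sqrt(1.0 - spec.rho**2) * rng.standard_normal(n)

    cols: dict[str, np.ndarray] = {}
    for j, name in enumerate(TONGUE_PARAMS):
        loc, scale = _TONGUE_SCALES[name]
        z = spec.tongue_loading[j] * u + spec.noise_sd * rng.standard_normal(n)
        cols[name] = loc + scale * z
    for j, name in enumerate(PULSE_BASE_PARAMS):
        loc, scale = _PULSE_SCALES[name]
        z = spec.pulse_loading[j] * v + spec.noise_sd * rng.standard_normal(n)
        cols[name] = loc + scale * z

    cols["h4/h1"] = cols["h4"] / cols["h1"]
    cols["h3/h1"] = cols["h3"] / cols["h1"]
    cols["w2/t"] = cols["w2"] / cols["t"]
    cols["h1/t1"] = cols["h1"] / cols["t1"]

    ids = [f"S{i:05d}" for i in range(n)]
    data = pd.DataFrame(cols, index=ids)
    return TonguePulseTable(data, list(TONGUE_PARAMS), PULSE_BASE_PARAMS + PULSE_RATIOS)


def default_feature_catalog() -> list[Feature]:
    """The default symptom/index catalog (codes and labels of the study's tables)."""
    symptoms = [
        ("FA1", "Fatigue", 0.30),
        ("TC1", "White tongue coating", 0.12),
        ("TC2", "Yellow tongue coating", 0.10),
        ("TC6", "Thick coating", 0.08),
        ("TC11", "Greasy coating", 0.07),
        ("LP1", "Headache", 0.10),
        ("QP1", "Sour", 0.09),
        ("EM3", "Irritability", 0.10),
        ("EM6", "Insomnia", 0.11),
        ("EM7", "Dreaminess", 0.10),
        ("THA4", "Chest distress", 0.07),
        ("HE1", "Dizziness", 0.09),
        ("HE13", "Xerophthalmia", 0.07),
        ("PU15", "Wiry pulse", 0.06),
        ("ST2", "Poor appetite", 0.08),
        ("ST9", "Abdominal distension", 0.06),
        ("LB2", "Soreness of waist", 0.07),
        ("CO3", "Aversion to cold", 0.05),
        ("SW1", "Spontaneous sweating", 0.05),
        ("TH1", "Thirst", 0.08),
    ]
    indexes = [
        ("SBP", "Systolic blood pressure", 0.01),
        ("DBP", "Diastolic blood pressure", 0.01),
        ("BMI", "Body mass index", 0.01),
        ("BRT8", "Hemoglobin", 0.01),
        ("BRT10", "Hematocrit", 0.01),
        ("BRT12", "Percentage of monocyte", 0.01),
        ("BRT13", "Basophil", 0.01),
        ("BRT20", "Platelet distribution width", 0.01),
        ("RUT5", "PH of urine", 0.01),
        ("BI15", "Uric acid", 0.01),
        ("BI5", "Fasting glucose", 0.01),
        ("BI8", "Triglyceride", 0.01),
    ]
    return (
        [Feature(c, lab, "symptom", p) for c, lab, p in symptoms]
        + [Feature(c, lab, "index", p) for c, lab, p in indexes]
    )


def default_latent_factors() -> list[LatentFactor]:
    """Latent syndrome factors producing group-structured co-occurrence."""
    return [
        LatentFactor(
            "fatigue_syndrome",
            loadings={"FA1": 0.90, "TC1": 0.45, "LP1": 0.40, "QP1": 0.38, "EM7": 0.36,
                      "EM3": 0.35, "THA4": 0.30, "HE13": 0.28, "TC6": 0.28, "EM6": 0.34,
                      "TC2": 0.25},
            activation={"healthy": 0.05, "subhealth": 0.85, "disease": 0.70},
        ),
        LatentFactor(
            "damp_phlegm",
            loadings={"TC6": 0.40, "TC11": 0.42, "TC2": 0.35, "PU15": 0.35, "HE1": 0.38,
                      "ST2": 0.25, "ST9": 0.22},
            activation={"healthy": 0.05, "subhealth": 0.30, "disease": 0.60},
        ),
        LatentFactor(
            "metabolic_disease",
            loadings={"SBP": 0.55, "DBP": 0.45, "BMI": 0.45, "BI15": 0.35, "BI5": 0.35,
                      "BI8": 0.40, "RUT5": 0.25},
            activation={"healthy": 0.0, "subhealth": 0.0, "disease": 0.75},
        ),
        LatentFactor(
            "hematologic",
            loadings={"BRT13": 0.50, "BRT20": 0.48, "BRT12": 0.45, "BRT8": 0.35, "BRT10": 0.35},
            activation={"healthy": 0.0, "subhealth": 0.0, "disease": 0.50},
        ),
    ]


def default_cohort_spec(seed: int = 0, n_healthy: int = 742, n_subhealth: int = 361,
                        n_disease: int = 1529) -> CohortSpec:
    """Default cohort: the study's group sizes, catalog and latent factors."""
    return CohortSpec(
        n_healthy=n_healthy,
        n_subhealth=n_subhealth,
        n_disease=n_disease,
        features=default_feature_catalog(),
        factors=default_latent_factors(),
        disease_subgroups=[("hypertension", 311), ("diabetes", 157),
                           ("hyperlipemia", 518), ("fatty_liver", 442)],
        seed=seed,
    )


#: Planted first canonical correlations per group: the disease and healthy
#: groups carry a real tongue-pulse association, the sub-health group none.
DEFAULT_GROUP_RHO = {"healthy": 0.475, "subhealth": 0.0, "disease": 0.42}


def default_tongue_pulse_spec(group: str = "disease", seed: int = 0,
                              n_subjects: int | None = None) -> TonguePulseSpec:
    """Default tongue/pulse spec for one study group (n matches the study's CCA sizes)."""
    sizes = {"healthy": 551, "subhealth": 252, "disease": 1160}
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    return TonguePulseSpec(
        n_subjects=sizes[group] if n_subjects is None else n_subjects,
        rho=DEFAULT_GROUP_RHO[group],
        seed=seed,
    )


def write_cohort_csv(cohort: Cohort, path: str | Path) -> None:
    cohort.to_frame().to_csv(path, index_label="id", float_format="%.6g")


def write_tongue_pulse_csv(table: TonguePulseTable, path: str | Path) -> None:
    table.data.to_csv(path, index_label="id", float_format="%.8g")


def read_cohort_csv(path: str | Path, features: list[Feature]) -> Cohort:
    """Read a cohort written by :func:`write_cohort_csv` (or real data in that schema)."""
    df = pd.read_csv(path, index_col="id")
    codes = [f.code for f in features]
    matrix = BinaryCohortMatrix(df[codes].astype(np.int8), list(features))
    sub = df["subgroup"] if "subgroup" in df.columns else None
    return Cohort(matrix, df["group"], df["h20"], df["fatigue"].astype(bool), sub)
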