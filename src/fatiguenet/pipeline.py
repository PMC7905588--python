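"""End-to-end study flow: cohort -> grouping -> networks -> IMC -> CCA.

``run_study`` executes the full analysis recipe on synthetic (or same-schema
user) data and writes every table, network and a manifest of sha256 hashes
into the output directory, so a run is reproducible from config + seed
alone. Artifacts deliberately contain no wall-clock information: equal
seeds give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from fatiguenet._version import __version__ as _pkg_version
from fatiguenet.cca import CCAResult, fit_cca, significance_test, structure_loadings
from fatiguenet.conet import build_network, filter_associations, normalize_weights, write_pajek
from fatiguenet.containers import TonguePulseTable
from fatiguenet.importance import CohesionParams, extract_core_subnetwork, rank_core
from fatiguenet.preprocessing import assign_groups, exclude_outlier_subjects
from fatiguenet.synthetic import (
    DEFAULT_GROUP_RHO,
    GROUPS,
    Cohort,
    CohortSpec,
    TonguePulseSpec,
    default_cohort_spec,
    gen_binary_cohort,
    gen_tongue_pulse,
    read_cohort_csv,
    write_cohort_csv,
    write_tongue_pulse_csv,
)

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Configuration of one full study run; every field has a default."""

    seed: int = 0
    out_dir: str | Path = "study_out"
    cohort_csv: str | Path | None = None       # load instead of generate
    n_healthy: int = 742
    n_subhealth: int = 361
    n_disease: int = 1529
    group_rho: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GROUP_RHO))
    cca_n: dict[str, int] = field(
        default_factory=lambda: {"healthy": 551, "subhealth": 252, "disease": 1160})
    core_k: int = 10
    assoc_mode: str = "threshold"
    assoc_threshold: float = 0.5
    assoc_top_k: int = 10
    fence_inner: float = 1.5
    fence_outer: float = 3.0
    cohesion: CohesionParams = field(default_factory=CohesionParams)

    def __post_init__(self) -> None:
        if self.core_k < 1:
            raise ValueError("core_k must be >= 1")
        if self.cohort_csv is not None and not Path(self.cohort_csv).exists():
            raise FileNotFoundError(self.cohort_csv)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if "cohesion" in raw and isinstance(raw["cohesion"], dict):
            raw["cohesion"] = CohesionParams(**raw["cohesion"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "cohort_csv": None if self.cohort_csv is None else str(self.cohort_csv),
            "n_healthy": self.n_healthy,
            "n_subhealth": self.n_subhealth,
            "n_disease": self.n_disease,
            "group_rho": {g: float(r) for g, r in self.group_rho.items()},
            "cca_n": {g: int(n) for g, n in self.cca_n.items()},
            "core_k": self.core_k,
            "assoc_mode": self.assoc_mode,
            "assoc_threshold": self.assoc_threshold,
            "assoc_top_k": self.assoc_top_k,
            "fence_inner": self.fence_inner,
            "fence_outer": self.fence_outer,
            "cohesion": {
                "strength_aggregation": self.cohesion.strength_aggregation,
                "edge_threshold": self.cohesion.edge_threshold,
                "disconnected_policy": self.cohesion.disconnected_policy,
            },
        }


@dataclass
class StudyReport:
    """In-memory results of one study run (all files also on disk)."""

    out_dir: Path
    group_sizes: dict[str, int]
    importance: dict[str, pd.DataFrame]        # e.g. "subhealth_symptom"
    associations: dict[str, pd.DataFrame]
    cca: dict[str, CCAResult]
    cca_summary: pd.DataFrame
    exclusions: dict[str, pd.DataFrame]
    manifest: dict


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, float3: tuple[str, ...] = ()) -> None:
    out = df.copy()
    for col in float3:  # 3-decimal presentation, full precision kept in memory
        out[col] = out[col].map(lambda v: f"{v:.3f}")
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_study(config: StudyConfig | None = None) -> StudyReport:
    """Run the full study flow and write all artifacts + manifest.

    Stages: generate/load cohort -> assign groups from H20 score, fatigue
    flag and binarized indexes -> per-group symptom network, IMC ranking,
    core extraction and association filtering -> index and combined
    symptom-index networks for the disease group -> tongue/pulse outlier
    exclusion and per-group CCA.
    """
    config = config or StudyConfig()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    # --- cohort ---------------------------------------------------------
    spec = default_cohort_spec(seed=config.seed, n_healthy=config.n_healthy,
                               n_subhealth=config.n_subhealth, n_disease=config.n_disease)
    if config.cohort_csv is not None:
        cohort = read_cohort_csv(config.cohort_csv, spec.features)
    else:
        cohort = gen_binary_cohort(spec)
    cohort_path = out / "cohort.csv"
    write_cohort_csv(cohort, cohort_path)
    files.append(cohort_path)

    # --- grouping -------------------------------------------------------
    index_codes = [f.code for f in cohort.matrix.features if f.block == "index"]
    has_disease = cohort.matrix.data[index_codes].sum(axis=1) > 0
    groups = assign_groups(cohort.h20, cohort.fatigue, has_disease)
    sizes = {g: int((groups == g).sum()) for g in (*GROUPS, "unclassified")}
    logger.info("group sizes after classification: %s", sizes)
    gpath = out / "groups.csv"
    groups.to_frame().assign(h20=cohort.h20.round(2)).to_csv(gpath, index_label="id")
    files.append(gpath)

    importance: dict[str, pd.DataFrame] = {}
    associations: dict[str, pd.DataFrame] = {}

    def analyse_block(group: str, blocks: tuple[str, ...], tag: str,
                      cross: bool = False) -> tuple[pd.DataFrame | None, list[str]]:
        members = groups[groups == group].index
        if len(members) == 0:
            logger.warning("group %s is empty after classification; skipping %s", group, tag)
            return None, []
        sub_matrix = cohort.matrix.subset(blocks)
        sub_matrix = type(sub_matrix)(sub_matrix.data.loc[members], sub_matrix.features)
        net = build_network(sub_matrix)
        if not net.triples:
            logger.warning("group %s has no co-occurrences in %s; skipping", group, tag)
            return None, []
        table, core = rank_core(net, config.cohesion, k=config.core_k)
        importance[f"{group}_{tag}"] = table
        _write_tsv(table, out / f"{group}_{tag}_importance.tsv", float3=("imc",))
        files.append(out / f"{group}_{tag}_importance.tsv")
        core_net = extract_core_subnetwork(net, core)
        write_pajek(core_net, out / f"{group}_{tag}_core.net")
        files.append(out / f"{group}_{tag}_core.net")
        assoc = normalize_weights(net)
        mode_value = (config.assoc_threshold if config.assoc_mode == "threshold"
                      else config.assoc_top_k)
        assoc = filter_associations(assoc, config.assoc_mode, mode_value, cross_block=cross)
        associations[f"{group}_{tag}"] = assoc
        _write_tsv(assoc, out / f"{group}_{tag}_assoc.tsv", float3=("normalized_weight",))
        files.append(out / f"{group}_{tag}_assoc.tsv")
        return table, core

    # symptom networks for every group; index + combined for the disease group
    core_sets: dict[str, list[str]] = {}
    for group in GROUPS:
        _, core = analyse_block(group, ("symptom",), "symptom")
        core_sets[f"{group}_symptom"] = core
    _, disease_index_core = analyse_block("disease", ("index",), "index")
    core_sets["disease_index"] = disease_index_core

    if core_sets["disease_symptom"] and disease_index_core:
        members = groups[groups == "disease"].index
        combined = build_network(
            type(cohort.matrix)(cohort.matrix.data.loc[members], cohort.matrix.features))
        assoc = normalize_weights(combined)
        assoc = filter_associations(assoc, "top_k", config.assoc_top_k, cross_block=True)
        associations["disease_combined"] = assoc
        _write_tsv(assoc, out / "disease_combined_assoc.tsv", float3=("normalized_weight",))
        files.append(out / "disease_combined_assoc.tsv")
        core_net, roles = extract_core_subnetwork(
            combined, core_sets["disease_symptom"], disease_index_core)
        write_pajek(core_net, out / "disease_combined_core.net")
        files.append(out / "disease_combined_core.net")
        role_df = pd.DataFrame(
            [{"pair_a": a, "pair_b": b, "role": r} for (a, b), r in sorted(roles.items())])
        _write_tsv(role_df, out / "disease_combined_core_roles.tsv")
        files.append(out / "disease_combined_core_roles.tsv")

    # --- tongue/pulse CCA per group -------------------------------------
    cca_results: dict[str, CCAResult] = {}
    exclusions: dict[str, pd.DataFrame] = {}
    summary_rows = []
    for gi, group in enumerate(GROUPS):
        n_g = config.cca_n.get(group, 0)
        if n_g == 0:
            logger.warning("no tongue/pulse subjects configured for %s; skipping CCA", group)
            continue
        tp_spec = TonguePulseSpec(n_subjects=n_g, rho=config.group_rho[group],
                                  seed=(config.seed * 7 + 1000 + gi) % (2**31))
        table = gen_tongue_pulse(tp_spec)
        write_tongue_pulse_csv(table, out / f"{group}_tongue_pulse.csv")
        files.append(out / f"{group}_tongue_pulse.csv")
        kept, log = exclude_outlier_subjects(table, config.fence_inner, config.fence_outer)
        exclusions[group] = log
        _write_tsv(log, out / f"{group}_exclusions.tsv")
        files.append(out / f"{group}_exclusions.tsv")
        result = fit_cca(kept.tongue, kept.pulse)
        cca_results[group] = result
        loadings = structure_loadings(result, kept.tongue, kept.pulse)
        _write_tsv(loadings, out / f"{group}_cca_loadings.tsv")
        files.append(out / f"{group}_cca_loadings.tsv")
        test = significance_test(result)
        summary_rows.append({
            "group": group,
            "n": len(kept.data),
            "n_excluded": len(table.data) - len(kept.data),
            "first_canonical_correlation": float(result.correlations[0]),
            "p_value": float(test["p_value"].iloc[0]),
        })
        logger.info("CCA %s: r1=%.3f p=%.3g (n=%d)", group, result.correlations[0],
                    test["p_value"].iloc[0], len(kept.data))
    cca_summary = pd.DataFrame(summary_rows)
    _write_tsv(cca_summary, out / "cca_summary.tsv")
    files.append(out / "cca_summary.tsv")

    # --- manifest -------------------------------------------------------
    manifest = {
        "package_version": _pkg_version,
        "seed": config.seed,
        "config": config.to_dict(),
        "group_sizes": sizes,
        "files": {f.name: _sha256(f) for f in sorted(set(files))},
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))

    return StudyReport(
        out_dir=out,
        group_sizes=sizes,
        importance=importance,
        associations=associations,
        cca=cca_results,
        cca_summary=cca_summary,
        exclusions=exclusions,
        manifest=manifest,
    )
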