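"""End-to-end orchestration: simulate -> histology -> multivariate ->
enrichment -> microbiome, with a machine-readable report.

A single mandatory seed drives every stochastic stage through independent
substreams spawned from one ``SeedSequence``, so toggling one stage on or
off never perturbs another stage's draws, and identical configurations
yield byte-identical reports.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrich, histo, io, microbiome, mva, synth

logger = logging.getLogger(__name__)

_STAGES = ("histo", "mva", "enrich", "microbiome")
# fixed substream indices per stage, so toggles do not shift other stages
_SUBSTREAM = {"cohort": 0, "treated": 1, "organoid": 2, "enrich": 3, "microbiome": 4}


@dataclass
class RunConfig:
    seed: int = 0
    cohort: synth.CohortConfig = field(default_factory=synth.CohortConfig)
    stages: tuple[str, ...] = _STAGES
    treatment_duration_h: float = 48.0
    n_treated: int = 8
    plsr_components: int = 2
    cytokines_only_plsr: bool = True
    classify_threshold_um: float = 300.0
    continuous_fraction: float = 0.8
    control_fraction: float = 0.1
    gsea_n_perm: int = 500
    microbiome_depth: int = 20_000
    n_animals_per_microbiome_group: int = 6

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.treatment_duration_h < 0 or self.n_treated < 0:
            raise ValueError("treatment settings must be non-negative")
        if self.plsr_components < 1 or self.gsea_n_perm < 1:
            raise ValueError("plsr_components and gsea_n_perm must be >= 1")
        # a single seed governs everything; the cohort inherits it
        self.cohort = replace(self.cohort, seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort_raw = raw.pop("cohort", {})
        for key in ("hyperplasia_range_um", "focal_score_range", "focal_window_fraction"):
            if key in cohort_raw:
                cohort_raw[key] = tuple(cohort_raw[key])
        for key in ("analyte_names", "analyte_units", "analyte_baselines",
                    "inflammation_loading", "noise_sd", "goblet_elevated"):
            if key in cohort_raw:
                cohort_raw[key] = tuple(cohort_raw[key])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(cohort=synth.CohortConfig(**cohort_raw), **raw)

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(payload), fh, sort_keys=True)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _stage_rng(config: RunConfig, stage: str) -> np.random.Generator:
    children = np.random.SeedSequence(config.seed).spawn(len(_SUBSTREAM) + 1)
    return np.random.default_rng(children[_SUBSTREAM[stage] + 1])


def run_all(config: RunConfig, outdir) -> dict:
    """Run every enabled stage in order, writing intermediates and a report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "run_config.yaml")
    report: dict = {"seed": config.seed, "stages": list(config.stages)}
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    cohort = synth.generate_cohort(config.cohort)
    tables = synth.cohort_tables(cohort, config.cohort)
    for name, df in tables.items():
        io.write_table(df, outdir / f"{name}.tsv")
    report["cohort"] = {
        "n_animals": len(cohort),
        "class_counts": pd.Series([a.true_class for a in cohort]).value_counts().to_dict(),
    }
    timings["simulate"] = time.perf_counter() - t0

    profiles = {a.id: histo.clean_measurements(a.crypt_profile) for a in cohort}
    if "histo" in config.stages:
        t0 = time.perf_counter()
        try:
            report["histo"] = _run_histo(config, cohort, profiles, outdir)
        except Exception as err:
            raise RuntimeError(f"stage 'histo' failed: {err}") from err
        timings["histo"] = time.perf_counter() - t0

    if "mva" in config.stages:
        t0 = time.perf_counter()
        try:
            report["mva"] = _run_mva(config, cohort, profiles, outdir)
        except Exception as err:
            raise RuntimeError(f"stage 'mva' failed: {err}") from err
        timings["mva"] = time.perf_counter() - t0

    if "enrich" in config.stages:
        t0 = time.perf_counter()
        try:
            report["enrich"] = _run_enrich(config, outdir)
        except Exception as err:
            raise RuntimeError(f"stage 'enrich' failed: {err}") from err
        timings["enrich"] = time.perf_counter() - t0

    if "microbiome" in config.stages:
        t0 = time.perf_counter()
        try:
            report["microbiome"] = _run_microbiome(config, outdir)
        except Exception as err:
            raise RuntimeError(f"stage 'microbiome' failed: {err}") from err
        timings["microbiome"] = time.perf_counter() - t0

    for stage, secs in timings.items():
        logger.info("stage %s took %.3f s", stage, secs)
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(_round_floats(_plain(report)), indent=1, sort_keys=True))
    logger.info("pipeline complete; report at %s", report_path)
    return report


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _run_histo(config: RunConfig, cohort, profiles, outdir: Path) -> dict:
    binned = [histo.bin_profile(p) for p in profiles.values()]
    labels = [a.true_class for a in cohort]
    groups = histo.group_profile(binned, labels)
    io.write_table(groups, outdir / "binned_profiles.tsv")

    calls = {
        a.id: histo.classify_extent(
            profiles[a.id],
            baseline_um=config.cohort.baseline_crypt_um,
            hyper_threshold_um=config.classify_threshold_um,
            continuous_fraction=config.continuous_fraction,
            control_fraction=config.control_fraction,
        )
        for a in cohort
    }
    calls_df = pd.DataFrame(
        {"animal_id": list(calls), "true_class": labels, "called_class": list(calls.values())}
    )
    io.write_table(calls_df, outdir / "class_calls.tsv")
    confusion = (
        calls_df.groupby(["true_class", "called_class"]).size().unstack(fill_value=0)
    )
    diag = sum(
        confusion.loc[c, c] for c in confusion.index if c in confusion.columns
    )

    heights = np.array([profiles[a.id].mean_distal_height() for a in cohort])
    weight_loss = np.array([a.weight_loss_score for a in cohort])
    cd45 = np.array([sum(a.infiltrate_fractions.values()) for a in cohort])
    rs, ps, _ = histo.correlate(heights, cd45, method="spearman")
    rp, pp, _ = histo.correlate(heights, weight_loss, method="pearson")
    corr = pd.DataFrame(
        {
            "pair": ["height_vs_cd45", "height_vs_weight_loss"],
            "method": ["spearman", "pearson"],
            "r": [rs, rp],
            "p": [ps, pp],
        }
    )
    io.write_table(corr, outdir / "correlations.tsv")
    return {
        "confusion": {f"{t}->{c}": int(n) for (t, c), n in confusion.stack().items()},
        "diagonal_fraction": float(diag / len(cohort)),
        "height_vs_cd45_spearman_r": rs,
        "height_vs_weight_loss_pearson_r": rp,
    }


def _baseline_models(config: RunConfig, cohort, profiles):
    panel = synth.cohort_panel(cohort, config.cohort)
    heights = np.array([profiles[a.id].mean_distal_height() for a in cohort])
    transforms = mva.transforms_from_units(config.cohort.analyte_units)
    pre = mva.fit_preprocessor(panel, dict(zip(config.cohort.analyte_names, transforms)))
    pca = mva.fit_pca(panel, pre, k=min(5, len(cohort) - 1))
    if config.cytokines_only_plsr:
        cyto = [a for a, u in zip(config.cohort.analyte_names, config.cohort.analyte_units)
                if u == "pg/ml"]
        plsr_panel = panel[cyto]
        plsr_pre = mva.fit_preprocessor(plsr_panel, "log1p")
    else:
        plsr_panel, plsr_pre = panel, pre
    plsr = mva.fit_plsr(plsr_panel, heights, plsr_pre, k=config.plsr_components)
    return panel, heights, pca, plsr, plsr_panel


def _run_mva(config: RunConfig, cohort, profiles, outdir: Path) -> dict:
    panel, heights, pca, plsr, plsr_panel = _baseline_models(config, cohort, profiles)
    labels = [a.true_class for a in cohort]

    (outdir / "pca_model.json").write_text(mva.model_to_json(pca))
    (outdir / "plsr_model.json").write_text(mva.model_to_json(plsr))
    r2 = mva.score_phenotype_fit(pca.scores[:, 0], heights)
    regions = mva.fit_class_regions(plsr.scores, labels)

    # project a treated sub-cohort of continuous animals onto the frozen model
    treated_src = [a for a in cohort if a.true_class == "continuous"]
    rng = _stage_rng(config, "treated")
    extra_needed = max(0, config.n_treated - len(treated_src))
    if extra_needed:
        extra_cfg = replace(
            config.cohort,
            n_control=0, n_focal=0, n_continuous=extra_needed,
            seed=int(rng.integers(2**31 - 1)),
        )
        treated_src = treated_src + synth.generate_cohort(extra_cfg)
    treated_src = treated_src[: config.n_treated]
    model = synth.default_treatment(config.cohort)
    treated = synth.apply_treatment(treated_src, model, config.treatment_duration_h, config.cohort)
    treated_panel = synth.cohort_panel(treated, config.cohort)[list(plsr_panel.columns)]
    treated_scores = mva.project(plsr, treated_panel)
    treated_calls = [mva.assign_class(s, regions) for s in treated_scores.to_numpy()]
    io.write_table(
        treated_scores.assign(assigned_class=treated_calls).reset_index(names="animal_id"),
        outdir / "treated_projection.tsv",
    )

    # organoid condition panels projected onto the same cytokine model
    orng = _stage_rng(config, "organoid")
    organoid_rows, organoid_ids = [], []
    for condition in synth.ORGANOID_CONDITIONS:
        for rep in range(3):
            organoid_rows.append(synth.sample_organoid_panel(condition, config.cohort, orng))
            organoid_ids.append(f"{condition}_{rep + 1}")
    organoid_panel = pd.DataFrame(
        organoid_rows, index=organoid_ids, columns=list(config.cohort.analyte_names)
    )[list(plsr_panel.columns)]
    organoid_scores = mva.project(plsr, organoid_panel)
    organoid_calls = [mva.assign_class(s, regions) for s in organoid_scores.to_numpy()]
    io.write_table(
        organoid_scores.assign(assigned_class=organoid_calls).reset_index(names="sample_id"),
        outdir / "organoid_projection.tsv",
    )
    io.write_table(mva.top_loadings(plsr, n=20), outdir / "top_loadings.tsv")

    lv1_by_class = {
        c: float(np.mean(plsr.scores[np.asarray(labels) == c, 0]))
        for c in histo.CLASS_ORDER
    }
    return {
        "pca_explained_variance": pca.explained_variance.tolist(),
        "pc1_vs_height_r2": r2,
        "plsr_x_variance": plsr.explained_variance.tolist(),
        "plsr_y_variance": plsr.y_explained_variance.tolist(),
        "train_lv1_means": lv1_by_class,
        "treated_mean_lv1": float(treated_scores.iloc[:, 0].mean()),
        "treated_assigned": {
            c: treated_calls.count(c) for c in histo.CLASS_ORDER if c in treated_calls
        },
        "organoid_assigned": dict(zip(organoid_ids, organoid_calls)),
    }


def _run_enrich(config: RunConfig, outdir: Path) -> dict:
    rng = _stage_rng(config, "enrich")
    signatures = synth.default_signatures()
    mixtures, labels = synth.default_mixtures(rng=rng)
    expr = synth.sample_expression_matrix(mixtures, signatures, rng)
    io.write_table(expr.rename_axis("gene").reset_index(), outdir / "expression.tsv")
    sets = synth.default_gene_sets()
    enrich.write_gmt(sets, outdir / "gene_sets.gmt")
    results = enrich.gsea(
        expr, labels, sets,
        n_perm=config.gsea_n_perm, mode="auto",
        seed=np.random.SeedSequence(config.seed).spawn(10)[9],
        pos_label="inflamed",
    )
    table = enrich.results_table(results)
    io.write_table(table, outdir / "enrichment_results.tsv")

    # derive a cell-type-specific set from replicated pure-signature profiles
    reps, rep_labels = [], []
    for ct in synth.EPITHELIAL_TYPES[:4]:
        pure = pd.DataFrame(0.0, index=[f"{ct}_{i}" for i in range(3)],
                            columns=list(synth.EPITHELIAL_TYPES))
        pure[ct] = 1.0
        block = synth.sample_expression_matrix(pure, signatures, rng, noise_sd=0.15)
        reps.append(2.0 ** block)  # linear scale for fold-change thresholds
        rep_labels += [ct] * 3
    derived = enrich.derive_specific_set(
        pd.concat(reps, axis=1), rep_labels, target="enterocyte"
    )
    return {
        "nes": dict(zip(table["set"], table["nes"])),
        "fdr_q": dict(zip(table["set"], table["fdr_q"])),
        "derived_enterocyte_set_size": len(derived.genes),
    }


def _run_microbiome(config: RunConfig, outdir: Path) -> dict:
    rng = _stage_rng(config, "microbiome")
    profiles = synth.default_taxon_profiles()
    n = config.n_animals_per_microbiome_group
    meta_rows = []
    for group in ("control", "inflamed"):
        for i in range(n):
            animal = f"{group[:3]}{i + 1:02d}"
            for phase in ("pre", "post"):
                meta_rows.append({"sample_id": f"{animal}_{phase}", "animal_id": animal,
                                  "group": group, "phase": phase})
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    counts = synth.sample_counts_table(
        meta["group"], profiles, depth=config.microbiome_depth, rng=rng
    )
    io.write_table(counts.rename_axis("sample_id").reset_index(), outdir / "taxon_counts.tsv")
    comp = microbiome.relative_abundance(counts)
    D = microbiome.bray_curtis(comp)
    io.write_table(D.to_frame().rename_axis("sample_id").reset_index(),
                   outdir / "bray_curtis.tsv")
    ord_res = microbiome.pcoa(D, n_axes=3)
    io.write_table(ord_res.coordinates.rename_axis("sample_id").reset_index(),
                   outdir / "pcoa_coords.tsv")
    io.write_table(pd.DataFrame({"eigenvalue": ord_res.eigenvalues}),
                   outdir / "eigenvalues.tsv")
    paired = microbiome.paired_vs_between(D, meta)
    io.write_table(paired["summary"], outdir / "paired_summary.tsv")
    summary = paired["summary"].set_index("distribution")["mean"]
    axis1 = ord_res.coordinates["PCo1"]
    group_means = axis1.groupby(meta["group"]).mean()
    return {
        "mean_within_animal": float(summary["within_animal"]),
        "mean_between_same_group": float(summary["between_same_group"]),
        "mean_between_cross_group": float(summary["between_cross_group"]),
        "p_within_vs_same": paired["p_within_vs_same"],
        "p_same_vs_cross": paired["p_same_vs_cross"],
        "pcoa_axis1_group_separation": float(abs(group_means.diff().iloc[-1])),
        "pcoa_proportion_axis1": float(ord_res.proportion_explained[0]),
    }
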