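"""End-to-end pipeline: QC -> structure -> tree -> F_ST -> local ancestry ->
introgression -> mapping, driven by a YAML/JSON config with a single seed.

Stage seeds are fanned out deterministically as hash(seed, stage) so any
stage can be re-run in isolation; every output is listed in a manifest with
its SHA-256 hash, and byte-identical outputs are guaranteed for identical
(inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .admixture import align_components, apply_permutation, classify_accessions, fit_admixture
from .ancestry import (
    call_segments_all,
    mean_introgression,
    posterior_ancestry,
    refine_local_ancestry,
)
from .fst import fst_per_snp, fst_windows, pairwise_fst_table
from .io import apply_qc, read_panel, write_panel
from .mapping import admixture_map, bonferroni, kinship_matrix, mixed_model_assoc, read_phenotype_tsv
from .panel import ADMIXED
from .simulate import IntrogressionEvent, SimulationConfig, simulate_panel, simulate_phenotype
from .tree import allele_sharing_distance, nj_tree, write_newick

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class TraitConfig:
    name: str
    path: str | None = None          # phenotype TSV; None -> simulate
    donor: str | None = None         # donor component for admixture mapping
    methods: tuple[str, ...] = ("admixture_map", "mixed_model")
    causal_marker: int | None = None  # only for simulated traits
    effect: float = 1.0
    h2: float = 0.5


@dataclass
class PipelineConfig:
    """Validated, fully-defaulted pipeline configuration."""

    outdir: str = "paddymix_out"
    seed: int = 0
    # input: either a genotype file...
    genotype: str | None = None
    format: str = "tsv_matrix"
    het_policy: str = "het_as_missing"
    # ...or a simulation
    simulate: SimulationConfig | None = None
    # QC
    maf_min: float = 0.01
    max_missing: float = 0.2
    # structure
    K: int = 5
    restarts: int = 10
    tol: float = 1e-4
    max_iter: int = 2000
    admix_threshold: float = 0.80
    # introgression
    rate: float | str = "auto"
    rate_grid: tuple[float, ...] = (1e-9, 3e-9, 1e-8, 3e-8, 1e-7)
    min_snps: int = 5
    post_min: float = 0.5
    # F_ST
    window_bp: int = 100_000
    # mapping
    alpha: float = 0.05
    traits: tuple[TraitConfig, ...] = ()

    def validate(self) -> None:
        if self.K < 1:
            raise ConfigError("K: must be >= 1")
        if self.restarts < 1:
            raise ConfigError("restarts: must be >= 1")
        if not (0 <= self.maf_min < 0.5):
            raise ConfigError("maf_min: must be in [0, 0.5)")
        if self.window_bp <= 0:
            raise ConfigError("window_bp: must be positive")
        if self.min_snps < 1:
            raise ConfigError("min_snps: must be >= 1")
        if not (0 < self.admix_threshold <= 1):
            raise ConfigError("admix_threshold: must be in (0, 1]")
        if self.genotype is None and self.simulate is None:
            raise ConfigError("config needs either 'genotype' or 'simulate'")
        if self.genotype is not None and not Path(self.genotype).exists():
            raise ConfigError(f"genotype: file not found: {self.genotype}")
        for t in self.traits:
            if t.path is not None and not Path(t.path).exists():
                raise ConfigError(f"traits.{t.name}.path: file not found")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = dataclasses.asdict(self.simulate)
            d["simulate"]["introgression_events"] = [
                list(dataclasses.asdict(e).values())
                for e in self.simulate.introgression_events
            ]
        d["traits"] = [dataclasses.asdict(t) for t in self.traits]
        return d


_TOP_KEYS = {f.name for f in dataclasses.fields(PipelineConfig)}
_SIM_KEYS = {f.name for f in dataclasses.fields(SimulationConfig)}
_TRAIT_KEYS = {f.name for f in dataclasses.fields(TraitConfig)}


def parse_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML (or JSON) pipeline config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(
            f"unknown config key(s) {sorted(unknown)}; "
            f"valid keys: {sorted(_TOP_KEYS)}"
        )
    kwargs = dict(raw)
    if "simulate" in kwargs and kwargs["simulate"] is not None:
        kwargs["simulate"] = _sim_from_dict(kwargs["simulate"])
    if "traits" in kwargs:
        kwargs["traits"] = tuple(
            _trait_from_dict(t) for t in kwargs["traits"]
        )
    if "rate_grid" in kwargs:
        kwargs["rate_grid"] = tuple(float(x) for x in kwargs["rate_grid"])
    try:
        cfg = PipelineConfig(**_coerced(kwargs, PipelineConfig))
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    cfg.validate()
    return cfg


def _sim_from_dict(d: dict) -> SimulationConfig:
    unknown = set(d) - _SIM_KEYS
    if unknown:
        raise ConfigError(
            f"unknown simulate key(s) {sorted(unknown)}; valid: {sorted(_SIM_KEYS)}"
        )
    d = dict(d)
    for key in ("F_k", "pop_names", "n_pure_per_pop", "markers_per_chrom",
                "base_freq_range"):
        if key in d:
            d[key] = tuple(d[key])
    if "introgression_events" in d:
        d["introgression_events"] = tuple(
            ev if isinstance(ev, IntrogressionEvent) else IntrogressionEvent(*ev)
            for ev in d["introgression_events"]
        )
    try:
        return SimulationConfig(**d)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"simulate: {exc}") from exc


def _trait_from_dict(d: dict) -> TraitConfig:
    if isinstance(d, TraitConfig):
        return d
    unknown = set(d) - _TRAIT_KEYS
    if unknown:
        raise ConfigError(
            f"unknown trait key(s) {sorted(unknown)}; valid: {sorted(_TRAIT_KEYS)}"
        )
    d = dict(d)
    if "methods" in d:
        d["methods"] = tuple(d["methods"])
    try:
        return TraitConfig(**d)
    except TypeError as exc:
        raise ConfigError(f"traits: {exc}") from exc


def _coerced(kwargs: dict, cls) -> dict:
    """Light type checking with key-named errors."""
    out = {}
    types = {f.name: f.type for f in dataclasses.fields(cls)}
    for k, v in kwargs.items():
        t = types.get(k, "")
        if t == "int" and not isinstance(v, (int, np.integer)):
            raise ConfigError(f"{k}: expected an integer, got {v!r}")
        if t == "float" and not isinstance(v, (int, float, np.floating)):
            raise ConfigError(f"{k}: expected a number, got {v!r}")
        out[k] = v
    return out


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class StageError(RuntimeError):
    stage: str
    cause: Exception

    def __str__(self) -> str:
        return f"pipeline stage {self.stage!r} failed: {self.cause}"


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the output manifest (also written as
    manifest.json in the output directory)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "version": __version__,
        "artifacts": {},
        "inputs": {},
        "stages": [],
    }

    def emit(kind: str, path: Path) -> None:
        manifest["artifacts"].setdefault(kind, []).append(str(path))

    def run_stage(name: str, fn):
        t0 = time.time()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
            manifest["stages"].append({"stage": name, "status": "failed"})
            _write_manifest(manifest, outdir)
            raise StageError(name, exc) from exc
        manifest["stages"].append(
            {"stage": name, "status": "ok", "seconds": round(time.time() - t0, 3)}
        )
        logger.info("stage %s done in %.2fs", name, time.time() - t0)
        return result

    # --- load / simulate + QC -------------------------------------------
    truth = None

    def stage_qc():
        nonlocal truth
        if config.simulate is not None:
            panel, truth_ = simulate_panel(config.simulate)
            truth = truth_
        else:
            panel = read_panel(config.genotype, config.format, config.het_policy)  # type: ignore[arg-type]
            manifest["inputs"]["genotype"] = _sha256(config.genotype)
        panel = apply_qc(panel, config.maf_min, config.max_missing)
        path = outdir / "panel_qc.tsv"
        write_panel(panel, path, "tsv_matrix")
        emit("panel_qc", path)
        emit("panel_qc", Path(str(path) + ".map"))
        return panel

    panel = run_stage("qc", stage_qc)

    # --- structure -------------------------------------------------------
    def stage_structure():
        fit = fit_admixture(
            panel, config.K, n_restarts=config.restarts,
            seed=stage_seed(config.seed, "structure"),
            tol=config.tol, max_iter=config.max_iter,
        )
        names = [f"cluster{k}" for k in range(config.K)]
        if truth is not None and truth.Q_true.shape[1] == config.K:
            perm = align_components(fit, truth.Q_true)
            fit = apply_permutation(fit, perm)
            names = list(truth.pop_names)
        labels = classify_accessions(
            fit, config.admix_threshold, panel=panel, cluster_names=names
        )
        qp = outdir / "structure_Q.tsv"
        with open(qp, "w") as fh:
            fh.write("accession\tassigned\t" + "\t".join(names) + "\n")
            for i, acc in enumerate(panel.accession_ids):
                row = "\t".join(f"{x:.6f}" for x in fit.Q[i])
                fh.write(f"{acc}\t{labels[i]}\t{row}\n")
        pp = outdir / "structure_P.tsv"
        with open(pp, "w") as fh:
            fh.write("marker\t" + "\t".join(names) + "\n")
            for j, mid in enumerate(panel.marker_ids):
                fh.write(mid + "\t" + "\t".join(f"{x:.6f}" for x in fit.P[:, j]) + "\n")
        emit("structure", qp)
        emit("structure", pp)
        return fit, names, labels

    fit, cluster_names, labels = run_stage("structure", stage_structure)

    # --- tree ------------------------------------------------------------
    def stage_tree():
        D = allele_sharing_distance(panel)
        tree = nj_tree(D)
        path = outdir / "nj_tree.nwk"
        write_newick(tree, path)
        emit("tree", path)
        return D, tree

    D, _tree = run_stage("tree", stage_tree)

    # --- F_ST ------------------------------------------------------------
    def stage_fst():
        groups = [g for g in cluster_names if labels.count(g) >= 2]
        paths = []
        if len(groups) >= 2:
            res = fst_per_snp(panel, labels, groups)
            res = fst_windows(res, panel, config.window_bp)
            snp_path = outdir / "fst_per_snp.tsv"
            with open(snp_path, "w") as fh:
                fh.write("marker\tchrom\tpos_bp\tfst\n")
                for j, m in enumerate(panel.markers):
                    fh.write(f"{m.id}\t{m.chrom}\t{m.pos_bp}\t{_na(res.per_snp[j])}\n")
            win_path = outdir / "fst_windows.tsv"
            with open(win_path, "w") as fh:
                fh.write("chrom\tstart_bp\tend_bp\tfst\tn_snps\n")
                for chrom, lo, hi, f, k in res.windows:
                    fh.write(f"{chrom}\t{lo}\t{hi}\t{_na(f)}\t{k}\n")
            pair_path = outdir / "fst_pairwise.tsv"
            pair = pairwise_fst_table(panel, labels, groups)
            with open(pair_path, "w") as fh:
                fh.write("group1\tgroup2\tfst\n")
                for (a, b), f in pair.items():
                    fh.write(f"{a}\t{b}\t{f:.4f}\n")
            paths = [snp_path, win_path, pair_path]
            for p in paths:
                emit("fst", p)
        return paths

    run_stage("fst", stage_fst)

    # --- local ancestry --------------------------------------------------
    def stage_introgress():
        if config.rate == "auto":
            # full linkage-model fit: refined frequencies, cooled rate
            local = refine_local_ancestry(panel, fit)
        else:
            local = posterior_ancestry(panel, fit, float(config.rate))
        sum_path = outdir / "local_ancestry_mean.tsv"
        with open(sum_path, "w") as fh:
            fh.write("accession\t" + "\t".join(cluster_names) + "\n")
            means = local.posterior.mean(axis=1)
            for i, acc in enumerate(panel.accession_ids):
                fh.write(acc + "\t" + "\t".join(f"{x:.6f}" for x in means[i]) + "\n")
        emit("local_ancestry", sum_path)

        prof_path = outdir / "introgression_profiles.tsv"
        with open(prof_path, "w") as fh:
            fh.write("recipient\tdonor\tmarker\tmean_component\tthreshold_95\n")
            for recip in cluster_names:
                if recip not in labels:
                    continue
                for donor in cluster_names:
                    if donor == recip:
                        continue
                    prof = mean_introgression(
                        local, labels, recip, donor, pop_names=cluster_names
                    )
                    for j, mid in enumerate(panel.marker_ids):
                        fh.write(
                            f"{recip}\t{donor}\t{mid}\t{prof.values[j]:.6f}"
                            f"\t{prof.threshold_95:.6f}\n"
                        )
        emit("local_ancestry", prof_path)

        calls = call_segments_all(
            local, panel, labels, cluster_names,
            min_snps=config.min_snps, post_min=config.post_min,
        )
        tsv = outdir / "introgression_calls.tsv"
        with open(tsv, "w") as fh:
            fh.write("accession\tdonor\tchrom\tstart_bp\tend_bp\tn_snps\tmean_posterior\n")
            for c in calls:
                fh.write(
                    f"{c.accession_id}\t{c.donor_pop}\t{c.chrom}\t{c.start_bp}"
                    f"\t{c.end_bp}\t{c.n_snps}\t{c.mean_posterior:.4f}\n"
                )
        bed = outdir / "introgression_calls.bed"
        with open(bed, "w") as fh:
            for c in calls:
                # 1-based inclusive -> 0-based half-open
                fh.write(
                    f"{c.chrom}\t{c.start_bp - 1}\t{c.end_bp}\t"
                    f"{c.accession_id}:{c.donor_pop}\t{c.mean_posterior:.4f}\n"
                )
        emit("introgression", tsv)
        emit("introgression", bed)
        return local

    local = run_stage("introgress", stage_introgress)

    # --- mapping ---------------------------------------------------------
    def stage_mapping():
        paths = []
        kin = None
        admixed_ids = [
            a for a, lab in zip(panel.accession_ids, labels) if lab == ADMIXED
        ]
        for ti, trait in enumerate(config.traits):
            if trait.path is not None:
                pheno = read_phenotype_tsv(trait.path, trait.name)
                manifest["inputs"][f"phenotype:{trait.name}"] = _sha256(trait.path)
            else:
                if truth is None:
                    raise ValueError(
                        f"trait {trait.name!r} has no file and no simulation"
                    )
                causal = trait.causal_marker
                if causal is None:
                    raise ValueError(f"trait {trait.name!r} needs causal_marker")
                pheno = simulate_phenotype(
                    truth, panel, [(causal, trait.effect)], trait.h2,
                    seed=stage_seed(config.seed, f"trait:{trait.name}"),
                )
            for method in trait.methods:
                if method == "admixture_map":
                    if trait.donor is None or not admixed_ids:
                        logger.warning(
                            "skipping admixture mapping for %s (no donor/admixed)",
                            trait.name,
                        )
                        continue
                    res = admixture_map(
                        local, panel, pheno, admixed_ids, trait.donor,
                        pop_names=cluster_names,
                    )
                elif method == "mixed_model":
                    if kin is None:
                        kin = kinship_matrix(panel)
                    res = mixed_model_assoc(panel, pheno, fit.Q, kin)
                else:
                    raise ValueError(f"unknown mapping method {method!r}")
                res = bonferroni(res, config.alpha)
                path = outdir / f"mapping_{trait.name}_{method}.tsv"
                with open(path, "w") as fh:
                    fh.write(
                        f"# trait={trait.name} method={method} "
                        f"bonferroni={res.bonferroni_threshold:.4g} seed={config.seed}\n"
                    )
                    fh.write("marker\teffect\tse\tp_value\tsignificant\n")
                    for j, mid in enumerate(res.marker_ids):
                        sig = bool(res.significant[j]) if res.significant is not None else False
                        fh.write(
                            f"{mid}\t{_na(res.effect[j])}\t{_na(res.se[j])}"
                            f"\t{_na(res.p_value[j])}\t{int(sig)}\n"
                        )
                emit("mapping", path)
                paths.append(path)
        return paths

    run_stage("mapping", stage_mapping)

    # --- manifest --------------------------------------------------------
    for kind, files in manifest["artifacts"].items():
        manifest["artifacts"][kind] = [
            {"path": f, "sha256": _sha256(f)} for f in files
        ]
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def _na(x: float) -> str:
    return "NA" if (x is None or (isinstance(x, float) and np.isnan(x))) else f"{x:.6g}"


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
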