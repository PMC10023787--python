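"""End-to-end runs: design -> simulate -> decode -> enrich -> report.

Two workflow shapes are provided, mirroring the two ways a
trio-pharmacophore library is used:

* **de novo selection** (``run_simulated_denovo``): a full three-channel
  library is simulated, sequenced, decoded from reads, and per-channel
  enrichment folds are compared against the true capture weights.
* **affinity maturation / linker optimization**
  (``run_affinity_maturation``): single-member flanking sub-libraries with
  a full linker sub-library; the readout is qPCR Ct values converted to
  amounts through a standard curve and normalized against the no-target
  control.

Every stage is seeded from the one run seed, and a JSON manifest records
config, seeds, package version and outputs so a run is reproducible from
the manifest alone. Default problem sizes are desk scale (50 x 10 x 50,
pools of a few hundred thousand), mirroring the architecture of the full
883 x 30 x 890 library while keeping runs interactive.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decode import CountTable, count_reads
from .encoding import EncodingScheme, design_scheme, validate_assembly
from .enrichment import channel_enrichment, export_scatter, recovery_metrics
from .errors import ConfigError
from .library import ROLES, TDELibrary
from .qpcr import (
    StandardCurve,
    amounts_from_ct_table,
    control_normalized_enrichment,
    fit_standard_curve,
)
from .simulate import (
    BindingModel,
    generate_fastq,
    random_binding_model,
    resample_depth,
    simulate_capture,
    simulate_qpcr,
    simulate_selection,
    synthetic_library,
    write_fastq,
)

PRE_SAMPLE = "pre"
MODE_SAMPLES = {"target": "target", "no_target": "no_target", "no_ligand": "no_ligand"}


@dataclass
class RunConfig:
    """Configuration of one simulated run; YAML-loadable, flag-overridable."""

    size_a: int = 50
    size_b: int = 10
    size_c: int = 50
    pool_size: int = 200_000
    depth: int | None = None  # reads per channel; None -> one read per pool copy
    error_rate: float = 0.005
    seed: int = 7
    pseudocount: float = 1.0
    max_mm_index: int = 1
    max_mm_code: int = 1
    sigma_fragment: float = 1.0
    sigma_linker: float = 0.5
    beta: float = 1.0
    epsilon_direct: float = 0.1
    top_k: int = 5
    keep_fastq: bool = False
    # affinity maturation: known ligand pair strength on the flanking strands
    ligand_weight: float = 2.0
    capture_rate: float = 0.01
    # qPCR model (affinity-maturation runs)
    qpcr_slope: float = -3.3219
    qpcr_intercept: float = 30.0
    qpcr_noise_sd: float = 0.2
    qpcr_standards: tuple = (1e1, 1e2, 1e3, 1e4, 1e5, 1e6)

    def __post_init__(self):
        for name in ("size_a", "size_b", "size_c"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.pool_size < 0:
            raise ConfigError("pool_size must be >= 0")
        if not 0 <= self.error_rate < 1:
            raise ConfigError("error_rate must be in [0, 1)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.size_a, self.size_b, self.size_c)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "qpcr_standards" in data:
            data["qpcr_standards"] = tuple(float(x) for x in data["qpcr_standards"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["qpcr_standards"] = list(self.qpcr_standards)
        return d


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def write_manifest(outdir: Path, config: RunConfig, outputs: dict, metrics: dict) -> Path:
    manifest = {
        "tdel_version": __version__,
        "config": config.to_dict(),
        "config_sha256": _config_hash(config),
        "seed": config.seed,
        "outputs": {k: str(v) for k, v in outputs.items()},
        "metrics": metrics,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def _channel_counts(table: CountTable, sample: str, role: str, all_ids: Iterable[str]) -> dict:
    seen = table.channel(sample, role)
    return {i: seen.get(i, 0) for i in all_ids}


def simulate_samples(
    config: RunConfig,
    scheme: EncodingScheme,
    library: TDELibrary,
    modes: Iterable[str] = ("target",),
):
    """Simulate the naive pool plus one selection per requested mode.

    Returns (model, truths) where ``truths`` maps sample name (``pre``,
    ``target``, ``no_target``, ``no_ligand``) to member-level counts.
    """
    model = random_binding_model(
        config.shape,
        seed=config.seed + 11,
        sigma_fragment=config.sigma_fragment,
        sigma_linker=config.sigma_linker,
        beta=config.beta,
        epsilon_direct=config.epsilon_direct,
    )
    abundances = np.ones(config.shape)  # purified members: near-equimolar assembly
    truths = {}
    for k, mode in enumerate(modes):
        truths[mode] = simulate_selection(
            abundances, model.with_mode(mode), config.pool_size, seed=config.seed + 100 + k
        )
    return model, truths


def _sample_reads(config, scheme, library, sample, member_counts, seed):
    counts = member_counts
    if config.depth is not None:
        counts = resample_depth(member_counts, config.depth, seed=seed + 1)
    return generate_fastq(
        counts, scheme, library, sample, error_rate=config.error_rate, seed=seed
    )


def run_simulated_denovo(config: RunConfig, outdir: str | Path) -> dict:
    """Simulated de novo selection with per-channel recovery metrics.

    Writes per-channel count, enrichment and scatter CSVs, a ground-truth
    CSV, QC summary and a manifest. Returns a dict with output paths and
    metrics (per-channel Spearman of true weight vs decoded fold, top-hit
    recovery).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples = [PRE_SAMPLE, "target"]
    scheme = design_scheme(
        {"A": config.size_a, "B": config.size_b, "C": config.size_c}, samples, seed=config.seed
    )
    library = synthetic_library(scheme, seed=config.seed + 1)
    model, truths = simulate_samples(config, scheme, library, modes=("target",))
    truth = truths["target"]

    sample_counts = {PRE_SAMPLE: truth.pre_counts, "target": truth.post_counts}
    streams = [
        _sample_reads(config, scheme, library, s, c, seed=config.seed + 300 + i)
        for i, (s, c) in enumerate(sample_counts.items())
    ]
    outputs: dict[str, Path] = {}
    if config.keep_fastq:
        paths = []
        for s, stream in zip(sample_counts, streams):
            p = outdir / f"{s}.fastq"
            write_fastq(stream, p)
            outputs[f"fastq_{s}"] = p
            paths.append(p)
        table = count_reads(
            paths, scheme, max_mm_index=config.max_mm_index, max_mm_code=config.max_mm_code
        )
    else:
        table = count_reads(
            itertools.chain.from_iterable(streams),
            scheme,
            max_mm_index=config.max_mm_index,
            max_mm_code=config.max_mm_code,
        )

    scheme.save(outdir / "design.json")
    outputs["design"] = outdir / "design.json"
    table.to_csv(outdir / "counts.csv")
    outputs["counts"] = outdir / "counts.csv"
    table.qc_frame().to_csv(outdir / "qc_summary.csv", index=False)
    outputs["qc_summary"] = outdir / "qc_summary.csv"
    truth.to_frame(library).to_csv(outdir / "ground_truth.csv", index=False)
    outputs["ground_truth"] = outdir / "ground_truth.csv"

    metrics: dict = {"assembly": validate_assembly(scheme).stable, "channels": {}}
    enrichment_tables = {}
    for role in ROLES:
        ids = library.sub(role).ids
        pre = _channel_counts(table, PRE_SAMPLE, role, ids)
        post = _channel_counts(table, "target", role, ids)
        if sum(pre.values()) == 0 or sum(post.values()) == 0:
            # e.g. depth 0: report gracefully with empty tables
            empty = pd.DataFrame(
                columns=["code_id", "pre_count", "post_count", "pre_fraction",
                         "post_fraction", "fold", "infinite"]
            )
            empty.to_csv(outdir / f"enrichment_{role}.csv", index=False)
            outputs[f"enrichment_{role}"] = outdir / f"enrichment_{role}.csv"
            metrics["channels"][role] = None
            continue
        enr = channel_enrichment(pre, post, pseudocount=config.pseudocount)
        enrichment_tables[role] = enr
        enr.to_csv(outdir / f"enrichment_{role}.csv", index=False)
        outputs[f"enrichment_{role}"] = outdir / f"enrichment_{role}.csv"
        export_scatter(enr, outdir / f"scatter_{role}.csv")
        outputs[f"scatter_{role}"] = outdir / f"scatter_{role}.csv"
        metrics["channels"][role] = recovery_metrics(
            model.channel_truth(role), ids, enr, top_decoded=config.top_k
        )
    manifest = write_manifest(outdir, config, outputs, metrics)
    return {
        "scheme": scheme,
        "library": library,
        "model": model,
        "truth": truth,
        "counts": table,
        "enrichment": enrichment_tables,
        "metrics": metrics,
        "outputs": outputs,
        "manifest": manifest,
    }


def run_affinity_maturation(config: RunConfig, outdir: str | Path) -> dict:
    """Linker-optimization run with a qPCR readout and control normalization.

    Simulates target, no-target and no-ligand selections of a
    1 x n_b x 1 (or configured) library, reads out the SL-B channel by
    simulated qPCR, fits a standard curve on a known dilution series,
    converts Ct to amounts, and ranks linkers by target / no-target
    enrichment. The no-ligand selection is normalized the same way to show
    the ligand-pair effect.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    modes = ["target", "no_target", "no_ligand"]
    scheme = design_scheme(
        {"A": config.size_a, "B": config.size_b, "C": config.size_c},
        [PRE_SAMPLE, *modes],
        seed=config.seed,
    )
    library = synthetic_library(scheme, seed=config.seed + 1)
    # affinity maturation optimizes only the linker: the flanking sub-libraries
    # carry known ligands of fixed strength, linkers vary
    rand = random_binding_model(
        config.shape,
        seed=config.seed + 11,
        sigma_linker=config.sigma_linker,
        beta=config.beta,
        epsilon_direct=config.epsilon_direct,
    )
    model = BindingModel(
        w_a=np.full(config.size_a, config.ligand_weight),
        w_c=np.full(config.size_c, config.ligand_weight),
        l_b=rand.l_b,
        beta=config.beta,
        epsilon_direct=config.epsilon_direct,
    )
    # one shared input pool; each selection mode captures from it independently
    rng = np.random.default_rng(config.seed + 99)
    input_counts = rng.multinomial(config.pool_size, np.full(np.prod(config.shape), 1.0 / np.prod(config.shape))).reshape(config.shape)
    captured = {
        mode: simulate_capture(
            input_counts,
            model.with_mode(mode),
            seed=config.seed + 200 + k,
            capture_rate=config.capture_rate,
        )
        for k, mode in enumerate(modes)
    }

    ids_b = library.sub("B").ids
    true_curve = StandardCurve(slope=config.qpcr_slope, intercept=config.qpcr_intercept)

    # standards measured on the same instrument model, with the same noise
    standards = np.asarray(config.qpcr_standards, dtype=float)
    std_ct = simulate_qpcr(
        {f"std{i}": q for i, q in enumerate(standards)},
        true_curve,
        noise_sd=config.qpcr_noise_sd,
        seed=config.seed + 500,
    )
    fitted = fit_standard_curve(standards, std_ct["ct"].to_numpy())
    pd.DataFrame({"quantity": standards, "ct": std_ct["ct"]}).to_csv(
        outdir / "standards.csv", index=False
    )
    floor = float(standards.min()) * 0.1

    amounts = {}
    ct_frames = []
    axis_b = (0, 2)
    for k, mode in enumerate(modes):
        counts_b = captured[mode].sum(axis=axis_b)
        # eluted amount per linker is its captured copy number (curve units = copies)
        true_amounts = {i: float(c) for i, c in zip(ids_b, counts_b)}
        ct = simulate_qpcr(
            true_amounts, true_curve, noise_sd=config.qpcr_noise_sd, seed=config.seed + 600 + k
        )
        ct.insert(0, "sample", mode)
        ct_frames.append(ct)
        amt = amounts_from_ct_table(
            ct, fitted, calibrated_range=(float(standards.min()), float(standards.max()))
        )
        amounts[mode] = dict(zip(amt["code_id"], amt["amount"]))
    pd.concat(ct_frames, ignore_index=True).to_csv(outdir / "ct_table.csv", index=False)

    enr_target = control_normalized_enrichment(amounts["target"], amounts["no_target"], floor)
    enr_noligand = control_normalized_enrichment(amounts["no_ligand"], amounts["no_target"], floor)
    ranked = enr_target.sort_values(
        by=["ratio", "code_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    ranked.to_csv(outdir / "linker_ranking.csv", index=False)
    enr_noligand.to_csv(outdir / "no_ligand_enrichment.csv", index=False)

    metrics = {
        "curve": {
            "slope": fitted.slope,
            "intercept": fitted.intercept,
            "r_squared": fitted.r_squared,
            "efficiency": fitted.efficiency,
        },
        "mean_ratio_target": float(np.nanmean(enr_target["ratio"])),
        "mean_ratio_no_ligand": float(np.nanmean(enr_noligand["ratio"])),
        "top_linker": ranked["code_id"].iloc[0] if len(ranked) else None,
    }
    outputs = {
        "standards": outdir / "standards.csv",
        "ct_table": outdir / "ct_table.csv",
        "linker_ranking": outdir / "linker_ranking.csv",
        "no_ligand_enrichment": outdir / "no_ligand_enrichment.csv",
    }
    manifest = write_manifest(outdir, config, outputs, metrics)
    return {
        "scheme": scheme,
        "library": library,
        "model": model,
        "captured": captured,
        "input_counts": input_counts,
        "curve": fitted,
        "ranking": ranked,
        "no_ligand": enr_noligand,
        "metrics": metrics,
        "outputs": outputs,
        "manifest": manifest,
    }


def run_decode(
    fastq_paths: Iterable[str | Path],
    design_path: str | Path,
    outdir: str | Path,
    max_mm_index: int = 1,
    max_mm_code: int = 1,
    pre_sample: str | None = None,
    post_sample: str | None = None,
    pseudocount: float = 1.0,
) -> dict:
    """Decode real (or previously written) FASTQ files without simulation.

    Writes counts and QC CSVs; when pre/post sample names are given, also
    per-channel enrichment tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = [Path(p) for p in fastq_paths]
    for p in paths:
        if not p.exists():
            raise ConfigError(f"FASTQ file not found: {p}")
    scheme = EncodingScheme.load(design_path)
    table = count_reads(paths, scheme, max_mm_index=max_mm_index, max_mm_code=max_mm_code)
    table.to_csv(outdir / "counts.csv")
    table.qc_frame().to_csv(outdir / "qc_summary.csv", index=False)
    outputs = {"counts": outdir / "counts.csv", "qc_summary": outdir / "qc_summary.csv"}
    enrichment_tables = {}
    if pre_sample and post_sample:
        for role, cb in scheme.codebooks.items():
            ids = cb.ids
            pre = _channel_counts(table, pre_sample, role, ids)
            post = _channel_counts(table, post_sample, role, ids)
            if sum(pre.values()) == 0 or sum(post.values()) == 0:
                continue
            enr = channel_enrichment(pre, post, pseudocount=pseudocount)
            enr.to_csv(outdir / f"enrichment_{role}.csv", index=False)
            outputs[f"enrichment_{role}"] = outdir / f"enrichment_{role}.csv"
            enrichment_tables[role] = enr
    return {"counts": table, "enrichment": enrichment_tables, "outputs": outputs}
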