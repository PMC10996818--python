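"""File I/O, run configuration, and the end-to-end pipeline driver.

All on-disk formats are plain text: per-subject delimited matrices (rows =
channels, columns = time points) with a JSON manifest for cohorts; CSV for
events, ratings, QC reports and result tables; YAML for run configurations.
Every output carries the seed and parameters that produced it, and no stage
mutates its inputs on disk.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import Cohort, InvalidSpecError, NeurosyncError, RawIntensity

__all__ = [
    "read_cohort",
    "write_cohort",
    "read_raw_intensity",
    "write_raw_intensity",
    "read_events",
    "RunConfig",
    "run_pipeline",
    "PipelineError",
]

log = logging.getLogger("neurosync")


class PipelineError(NeurosyncError):
    """A pipeline stage failed; the message is tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write one TSV per subject plus a JSON manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, sid in enumerate(cohort.subjects):
        fname = f"{sid}.tsv"
        np.savetxt(out_dir / fname, cohort.data[i], delimiter="\t", fmt="%.12g")
        entries.append(
            {
                "id": sid,
                "file": fname,
                "group": None if cohort.group is None else cohort.group[i],
            }
        )
    manifest = {
        "subjects": entries,
        "sampling_rate": cohort.sampling_rate,
        "channel_ids": cohort.channel_ids,
        "seed": cohort.seed,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_cohort(manifest_path: str | Path) -> Cohort:
    """Read and validate a cohort from a manifest written by write_cohort."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    ids, groups, mats = [], [], []
    shape = None
    for entry in manifest["subjects"]:
        sid = entry["id"]
        if sid in ids:
            raise InvalidSpecError(f"duplicate subject id {sid!r}")
        f = base / entry["file"]
        if not f.exists():
            raise FileNotFoundError(f"subject {sid!r}: missing file {f}")
        mat = np.atleast_2d(np.loadtxt(f, delimiter="\t"))
        if shape is None:
            shape = mat.shape
        elif mat.shape != shape:
            raise InvalidSpecError(
                f"subject {sid!r}: shape {mat.shape} does not match {shape}"
            )
        ids.append(sid)
        groups.append(entry.get("group"))
        mats.append(mat)
    group = None if all(g is None for g in groups) else [g or "" for g in groups]
    return Cohort(
        subjects=ids,
        data=np.stack(mats),
        sampling_rate=float(manifest["sampling_rate"]),
        group=group,
        channel_ids=manifest.get("channel_ids"),
        seed=manifest.get("seed"),
    )


# --------------------------------------------------------------------------
# raw intensities and events
# --------------------------------------------------------------------------


def write_raw_intensity(raw: RawIntensity, out_dir: str | Path, stem: str = "raw") -> Path:
    """One delimited file per wavelength + JSON sidecar; returns sidecar path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for w, lam in enumerate(raw.wavelengths):
        fname = f"{stem}_{int(lam)}nm.tsv"
        np.savetxt(out_dir / fname, raw.intensity[w], delimiter="\t", fmt="%.12g")
        files.append(fname)
    sidecar = {
        "wavelengths": list(raw.wavelengths),
        "files": files,
        "sampling_rate": raw.sampling_rate,
        "channel_ids": raw.channel_ids,
        "adc_ceiling": raw.adc_ceiling,
    }
    path = out_dir / f"{stem}.json"
    path.write_text(json.dumps(sidecar, indent=2))
    return path


def read_raw_intensity(sidecar_path: str | Path) -> RawIntensity:
    sidecar_path = Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    base = sidecar_path.parent
    mats = [
        np.atleast_2d(np.loadtxt(base / f, delimiter="\t")) for f in meta["files"]
    ]
    return RawIntensity(
        wavelengths=tuple(meta["wavelengths"]),
        intensity=np.stack(mats),
        sampling_rate=float(meta["sampling_rate"]),
        channel_ids=meta.get("channel_ids"),
        adc_ceiling=meta.get("adc_ceiling"),
    )


def read_events(path: str | Path) -> pd.DataFrame:
    """Event table CSV with columns onset_s, duration_s, condition."""
    df = pd.read_csv(path)
    required = {"onset_s", "duration_s", "condition"}
    if not required.issubset(df.columns):
        raise InvalidSpecError(f"event table must have columns {sorted(required)}")
    return df


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Parameters of a full pipeline run; round-trips through YAML losslessly.

    Every stochastic stage has its own explicit seed; validation rejects a
    configuration that requests permutation inference without one.
    """

    out_dir: str = "neurosync_out"
    # synthetic cohort
    n_subjects: int = 16
    n_channels: int = 4
    n_timepoints: int = 500
    sampling_rate: float = 7.8
    coupling_structure: str = "annak"
    coupling_strength: float = 1.0
    simulate_seed: int | None = 0
    # inference
    n_perm: int = 1000
    perm_seed: int | None = 0
    isrsa_model: str = "annak"
    isrsa_method: str = "spearman"
    # emotion models
    emotion: str = "anger"
    ratings_seed: int | None = 0
    # misc
    qcod_threshold: float = 0.1
    max_saturation_s: float = 2.0
    filter_low: float = 0.005
    filter_high: float = 0.5
    pca_variance_fraction: float = 0.8
    verbosity: str = "INFO"

    def validate(self) -> None:
        for name in ("simulate_seed", "perm_seed", "ratings_seed"):
            if getattr(self, name) is None:
                raise InvalidSpecError(
                    f"{name} must be set: every stochastic stage needs an explicit seed"
                )
        if self.n_perm < 1:
            raise InvalidSpecError("n_perm must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


# --------------------------------------------------------------------------
# pipeline driver
# --------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate -> ISC -> IS-RSA -> emotion models and write all outputs.

    Returns a dict of output paths plus headline numbers.  Deterministic:
    rerunning with the same config produces byte-identical CSVs.
    """
    from . import __version__
    from .emotions import fit_two_part_zig
    from .isc import swp_two_sample_test
    from .isrsa import compare_similarity_models, isrsa_per_channel
    from .synth import (
        BehaviorCouplingSpec,
        RatingsGenSpec,
        SharedResponseSpec,
        simulate_coupled_cohort,
        simulate_ratings,
    )

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("simulate")
        rng = np.random.default_rng(config.simulate_seed)
        scores = rng.uniform(0, 100, config.n_subjects)
        base = SharedResponseSpec(
            n_subjects=config.n_subjects,
            n_timepoints=config.n_timepoints,
            sampling_rate=config.sampling_rate,
            shared_weights=0.3,
            noise_sd=1.0,
            n_channels=config.n_channels,
            seed=config.simulate_seed,
        )
        cohort, scores = simulate_coupled_cohort(
            BehaviorCouplingSpec(
                scores=scores,
                structure=config.coupling_structure,
                coupling_strength=config.coupling_strength,
                base=base,
            )
        )
        half = config.n_subjects // 2
        cohort.group = ["CT"] * half + ["MT"] * (config.n_subjects - half)
        manifest = write_cohort(cohort, out / "cohort")
        results["cohort_manifest"] = str(manifest)
    except NeurosyncError as e:
        raise PipelineError("simulate", str(e)) from e

    try:
        stage("isc")
        ct = cohort.subset(range(half))
        mt = cohort.subset(range(half, config.n_subjects))
        isc_rows = []
        perms = swp_two_sample_test(
            ct, mt, n_perm=config.n_perm, seed=config.perm_seed
        )
        from .isc import two_sample_statistic

        for res in perms:
            ch = res.extra["channel"]
            w, b, d = two_sample_statistic(ct, mt, ch)
            isc_rows.append(
                (ch, w, b, d, res.p_value, res.n_perm, res.seed)
            )
        isc_df = pd.DataFrame(
            isc_rows,
            columns=[
                "channel",
                "within_isc",
                "between_isc",
                "difference",
                "p",
                "n_perm",
                "seed",
            ],
        )
        isc_path = out / "isc_results.csv"
        isc_df.to_csv(isc_path, index=False)
        results["isc"] = str(isc_path)
    except NeurosyncError as e:
        raise PipelineError("isc", str(e)) from e

    try:
        stage("isrsa")
        fit_a = isrsa_per_channel(
            cohort, scores, model="annak", method=config.isrsa_method,
            n_perm=config.n_perm, seed=config.perm_seed,
        )
        fit_n = isrsa_per_channel(
            cohort, scores, model="nn", method=config.isrsa_method,
            n_perm=config.n_perm, seed=config.perm_seed,
        )
        isrsa_df = pd.concat([fit_a, fit_n], ignore_index=True)
        isrsa_path = out / "isrsa_results.csv"
        isrsa_df.to_csv(isrsa_path, index=False)
        comparison = compare_similarity_models(
            fit_a["r"].to_numpy(), fit_n["r"].to_numpy()
        )
        results["isrsa"] = str(isrsa_path)
        results["model_comparison_t"] = comparison.t_statistic
        results["model_comparison_p"] = comparison.p_value
    except NeurosyncError as e:
        raise PipelineError("isrsa", str(e)) from e

    try:
        stage("emotions")
        ratings = simulate_ratings(
            RatingsGenSpec(emotion=config.emotion, seed=config.ratings_seed)
        )
        ratings_path = out / "ratings.csv"
        ratings.to_csv(ratings_path, index=False)
        fit = fit_two_part_zig(ratings, emotion=config.emotion)
        fit_path = out / "emotion_fit.json"
        fit_path.write_text(json.dumps(fit.to_dict(), indent=2))
        results["ratings"] = str(ratings_path)
        results["emotion_fit"] = str(fit_path)
    except NeurosyncError as e:
        raise PipelineError("emotions", str(e)) from e

    provenance = {
        "version": __version__,
        "config": asdict(config),
    }
    prov_path = out / "provenance.json"
    prov_path.write_text(json.dumps(provenance, indent=2))
    results["provenance"] = str(prov_path)
    return results
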