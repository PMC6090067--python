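"""End-to-end reproducible run: simulate -> profile -> cluster -> brain age.

A single :class:`RunConfig` (one root seed) drives every stage; all
structured outputs are JSON or delimited text and are regenerated
byte-identically for a fixed config, so a run is fully self-describing via
its manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from . import __version__
from .cohort import (
    SEPARATED_SCALE,
    ClassLabel,
    default_cohort_spec,
    simulate_profiles,
)
from .clustering import brain_age, centroid_distances, gap_statistic, kmeans
from .io import (
    cohort_spec_from_json,
    read_swa_csv,
    write_centroids_csv,
    write_distance_matrix,
    write_swa_csv,
)
from .profiling import fit_projection, perceived_information, success_rate

logger = logging.getLogger("swa_brainage")


@dataclass
class RunConfig:
    """Configuration of a full analysis run (validated before any stage)."""

    outdir: Path
    seed: int = 0
    swa_path: Optional[Path] = None          # analyse an existing SWA matrix
    cohort_spec_path: Optional[Path] = None  # or simulate from a spec file
    scale: float = SEPARATED_SCALE           # or simulate the packaged default
    dims: int = 3
    priors: str = "uniform"
    regularization: float = 1e-6
    n_bootstrap: int = 100
    k_max: int = 6
    B: int = 100
    restarts: int = 1000
    reference_group: str = "6RW"

    def validate(self) -> None:
        if not 1 <= self.dims <= 12:
            raise ValueError(f"dims must be in [1, 12], got {self.dims}")
        if self.priors not in ("uniform", "empirical"):
            raise ValueError("priors must be 'uniform' or 'empirical'")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.k_max < 1 or self.B < 10 or self.restarts < 1 or self.n_bootstrap < 1:
            raise ValueError("k_max, B, restarts and n_bootstrap out of range")
        if self.regularization <= 0:
            raise ValueError("regularization must be positive")
        ClassLabel.parse(self.reference_group)
        for p in (self.swa_path, self.cohort_spec_path):
            if p is not None and not Path(p).exists():
                raise ValueError(f"referenced path does not exist: {p}")


@dataclass
class RunManifest:
    """Provenance of a completed run: config echo, digests, timings."""

    config: dict
    version: str
    stage_seconds: Dict[str, float]
    digests: Dict[str, str]
    summary: dict

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def run_full_analysis(config: RunConfig) -> RunManifest:
    """Execute every stage of the analysis and write all outputs.

    Stages: cohort (simulate or load), perceived information (LOO +
    bootstrap CI), template classification (50-50 split), Gap-statistic
    k-means clustering with per-group centroids, centroid distance matrix,
    and the brain-age report relative to the young-RW reference.  Any stage
    error aborts with the stage named.  Idempotent for fixed config + seed.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: Dict[str, float] = {}
    digests: Dict[str, str] = {}
    summary: dict = {}
    stage = "cohort"
    try:
        t0 = time.perf_counter()
        if config.swa_path is not None:
            profiles = read_swa_csv(config.swa_path)
        else:
            if config.cohort_spec_path is not None:
                spec = cohort_spec_from_json(config.cohort_spec_path)
                spec.seed = config.seed
            else:
                spec = default_cohort_spec(config.scale, seed=config.seed)
            profiles = simulate_profiles(spec)
        swa_out = outdir / "swa.csv"
        write_swa_csv(profiles, swa_out)
        digests["swa.csv"] = _sha256(swa_out)
        timings[stage] = time.perf_counter() - t0
        logger.info("cohort: %d profiles across %d groups",
                    len(profiles), len({p.label for p in profiles}))

        stage = "perceived_information"
        t0 = time.perf_counter()
        pi = perceived_information(
            profiles, d=config.dims, priors=config.priors,
            regularization=config.regularization,
            n_bootstrap=config.n_bootstrap, seed=config.seed,
        )
        _write_json(outdir / "pi.json", pi.to_dict())
        digests["pi.json"] = _sha256(outdir / "pi.json")
        timings[stage] = time.perf_counter() - t0
        summary["pi_bits"] = pi.pi
        logger.info("PI = %.3f bits (H(C) = %.3f, priors = %s, dims = %d)",
                    pi.pi, pi.class_entropy, config.priors, config.dims)

        stage = "classification"
        t0 = time.perf_counter()
        report = success_rate(
            profiles, d=config.dims, regularization=config.regularization,
            seed=config.seed,
        )
        _write_json(outdir / "classification.json", report.to_dict())
        digests["classification.json"] = _sha256(outdir / "classification.json")
        timings[stage] = time.perf_counter() - t0
        summary["success_rate_pct"] = 100.0 * report.success_rate
        logger.info("success rate = %.1f%%", 100 * report.success_rate)

        stage = "clustering"
        t0 = time.perf_counter()
        X = np.vstack([p.values for p in profiles])
        labels = [p.label for p in profiles]
        proj = fit_projection(X, config.dims)  # class-blind pooled PCA
        Z = proj.transform(X)
        gap = gap_statistic(Z, k_max=config.k_max, B=config.B,
                            restarts=config.restarts, seed=config.seed)
        solution = kmeans(Z, gap.k_star, restarts=config.restarts, seed=[config.seed, 4])
        group_centroids = _group_centroids(Z, labels, solution.assignments, solution.centroids)
        _write_json(outdir / "clusters.json", {
            "gap": gap.to_dict(),
            "k_star": gap.k_star,
            "inertia": solution.inertia,
            "assignments": solution.assignments.tolist(),
            "mouse_ids": [p.mouse_id for p in profiles],
        })
        write_centroids_csv(group_centroids, outdir / "centroids.csv")
        digests["clusters.json"] = _sha256(outdir / "clusters.json")
        digests["centroids.csv"] = _sha256(outdir / "centroids.csv")
        timings[stage] = time.perf_counter() - t0
        summary["k_star"] = gap.k_star
        logger.info("gap statistic: k* = %d (k_max = %d, B = %d, restarts = %d)",
                    gap.k_star, config.k_max, config.B, config.restarts)

        stage = "brain_age"
        t0 = time.perf_counter()
        matrix = centroid_distances(group_centroids)
        write_distance_matrix(matrix, outdir / "distance_matrix.tsv")
        ba = brain_age(matrix, config.reference_group)
        _write_json(outdir / "brainage.json", {
            "distance_matrix": matrix.to_dict(),
            **ba.to_dict(),
        })
        digests["distance_matrix.tsv"] = _sha256(outdir / "distance_matrix.tsv")
        digests["brainage.json"] = _sha256(outdir / "brainage.json")
        timings[stage] = time.perf_counter() - t0
        summary["attenuation_pct"] = {str(a): v for a, v in ba.attenuation_pct.items()}
        logger.info("brain-age attenuation (%% vs age-matched control): %s",
                    ba.attenuation_pct)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    cfg = {k: (str(v) if isinstance(v, Path) else v) for k, v in asdict(config).items()}
    manifest = RunManifest(
        config=cfg, version=__version__, stage_seconds=timings,
        digests=digests, summary=summary,
    )
    _write_json(outdir / "manifest.json", manifest.to_dict())
    return manifest


def _group_centroids(
    Z: np.ndarray,
    labels: List[ClassLabel],
    assignments: np.ndarray,
    cluster_centroids: np.ndarray,
) -> Dict[str, np.ndarray]:
    """One centroid per group.

    When the clustering recovers the groups (a bijective majority mapping
    between clusters and class labels), the k-means centroids are reported
    under their majority label; otherwise fall back to per-group means of
    the projected points.
    """
    present = sorted(set(labels))
    k = cluster_centroids.shape[0]
    mapping: Dict[int, ClassLabel] = {}
    if k == len(present):
        for j in range(k):
            members = [labels[i] for i in range(len(labels)) if assignments[i] == j]
            if members:
                mapping[j] = max(set(members), key=members.count)
        if len(set(mapping.values())) == k:
            return {mapping[j].short: cluster_centroids[j] for j in range(k)}
    logging.getLogger("swa_brainage").warning(
        "clusters do not map one-to-one onto groups; using per-group mean centroids"
    )
    out: Dict[str, np.ndarray] = {}
    for lab in present:
        idx = [i for i, l in enumerate(labels) if l == lab]
        out[lab.short] = Z[idx].mean(axis=0)
    return out
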