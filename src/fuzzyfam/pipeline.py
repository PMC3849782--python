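"""End-to-end pipeline: encode -> dissimilarity -> cluster/sweep -> report.

A :class:`RunConfig` (YAML or JSON on disk) names the inputs and all
method parameters; :func:`run_pipeline` executes the stages, writes every
intermediate artifact (feature matrix, dissimilarity matrix, sweep table,
membership matrix, hard labels) under the output directory and returns a
:class:`RunReport`. All randomness flows from the single top-level seed
through per-stage derived seeds so each stage is independently
reproducible.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .encoding import (
    DissimilarityMatrix,
    EncoderConfig,
    build_feature_matrix,
    dissimilarity_matrix,
)
from .fanny import FannyConfig, fanny_fit, harden
from .io import read_domain_hits, read_fasta
from .validation import DEFAULT_R_GRID, SelectRule, silhouette_samples, sweep_parameters

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised with the full list of configuration violations."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("; ".join(violations))


@dataclass
class RunConfig:
    fasta: str = ""
    domains: str | None = None
    domain_evalue: float = 1.0
    metric: str = "euclidean"
    peptide_lengths: tuple[int, ...] = (1, 2, 3, 4)
    mode: str = "sweep"  # "sweep" or "fixed"
    k: int = 2
    r: float = 2.0
    k_grid: tuple[int, ...] = (2, 3, 4)
    r_grid: tuple[float, ...] = DEFAULT_R_GRID
    select_rule: SelectRule = "mean"
    n_restarts: int = 5
    max_iter: int = 500
    tol: float = 1e-9
    seed: int = 0
    out_dir: str = "fuzzyfam_out"

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["peptide_lengths"] = list(self.peptide_lengths)
        d["k_grid"] = list(self.k_grid)
        d["r_grid"] = list(self.r_grid)
        return d


@dataclass
class RunReport:
    selected_k: int
    selected_r: float
    group_sizes: dict[int, int]
    n_objects: int
    membership_path: str
    labels_path: str
    sweep_path: str | None
    config: dict[str, Any]
    version: str
    wall_clock_s: float

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def validate_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML/JSON run configuration.

    Collects *all* violations before raising :class:`ConfigError`, so a
    user fixes a config in one pass rather than error by error.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError([f"config file {path} does not exist"])
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    violations: list[str] = []
    known = {f for f in RunConfig.__dataclass_fields__}
    for key in raw:
        if key not in known:
            violations.append(f"unknown config key {key!r}")
    cfg = RunConfig(**{k: v for k, v in raw.items() if k in known})
    cfg.peptide_lengths = tuple(cfg.peptide_lengths)
    cfg.k_grid = tuple(cfg.k_grid)
    cfg.r_grid = tuple(cfg.r_grid)
    if not cfg.fasta:
        violations.append("fasta path is required")
    elif not Path(cfg.fasta).exists():
        violations.append(f"fasta file {cfg.fasta} does not exist")
    if cfg.domains is not None and not Path(cfg.domains).exists():
        violations.append(f"domain-hit file {cfg.domains} does not exist")
    if cfg.mode not in {"sweep", "fixed"}:
        violations.append("mode must be 'sweep' or 'fixed'")
    if cfg.r <= 1:
        violations.append("membership exponent must exceed 1")
    if any(r <= 1 for r in cfg.r_grid):
        violations.append("every membership exponent in r_grid must exceed 1")
    if cfg.k < 2:
        violations.append("k must be >= 2")
    if any(k < 2 for k in cfg.k_grid):
        violations.append("every k in k_grid must be >= 2")
    if cfg.metric not in {"euclidean", "manhattan"}:
        violations.append("metric must be euclidean or manhattan")
    if cfg.fasta and Path(cfg.fasta).exists():
        n = sum(1 for line in open(cfg.fasta) if line.startswith(">"))
        grid_max = max(cfg.k_grid) if cfg.mode == "sweep" else cfg.k
        if grid_max >= n > 0:
            violations.append(
                f"largest k ({grid_max}) must be smaller than the number of "
                f"sequences ({n})"
            )
    if violations:
        raise ConfigError(violations)
    return cfg


def derive_seed(seed: int, stage: str) -> int:
    """Per-stage seed derived from the top-level seed (stable, < 2**31)."""
    tag = zlib.crc32(stage.encode()) % (2**31)
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] % (2**31))


def write_dissimilarity(D: DissimilarityMatrix, path: str | Path) -> None:
    pd.DataFrame(D.values, index=D.ids, columns=D.ids).to_csv(path)


def read_dissimilarity(path: str | Path) -> DissimilarityMatrix:
    df = pd.read_csv(path, index_col=0)
    return DissimilarityMatrix(list(df.index.astype(str)), df.to_numpy(float))


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute encode -> dissimilarity -> cluster/sweep -> harden -> report."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read inputs"
    try:
        records = read_fasta(config.fasta)
        hits = []
        if config.domains:
            hits, unknown = read_domain_hits(
                config.domains, config.domain_evalue,
                known_ids={r.id for r in records},
            )
            if unknown:
                logger.warning("domain hits for unknown sequence ids: %s", unknown)

        stage = "encode"
        enc = EncoderConfig(
            peptide_lengths=config.peptide_lengths,
            dissimilarity_metric=config.metric,  # type: ignore[arg-type]
        )
        space, vectors = build_feature_matrix(records, hits, enc)
        feat_rows = []
        for v in vectors:
            for n, block in v.blocks.items():
                feat_rows += [(v.owner_id, f"{n}:{k}", val) for k, val in block.items()]
            feat_rows += [(v.owner_id, f"domain:{m}", val)
                          for m, val in v.domain_block.items()]
        pd.DataFrame(feat_rows, columns=["seq_id", "feature_key", "value"]).to_csv(
            out / "features.tsv", sep="\t", index=False
        )

        stage = "dissimilarity"
        D = dissimilarity_matrix(space, vectors, config.metric)  # type: ignore[arg-type]
        write_dissimilarity(D, out / "dissimilarity.csv")

        stage = "cluster"
        sweep_path: str | None = None
        if config.mode == "sweep":
            sweep = sweep_parameters(
                D, config.k_grid, config.r_grid, config.select_rule,
                seed=derive_seed(config.seed, "sweep"),
                n_restarts=config.n_restarts, max_iter=config.max_iter,
                tol=config.tol,
            )
            if sweep.selected_k is None:
                raise RuntimeError("sweep produced no scoreable configuration")
            sweep.table.to_csv(out / "sweep.tsv", sep="\t", index=False)
            sweep_path = str(out / "sweep.tsv")
            k_sel, r_sel = sweep.selected_k, sweep.selected_r
            result = sweep.results[(k_sel, r_sel)]
        else:
            k_sel, r_sel = config.k, config.r
            result = fanny_fit(D, FannyConfig(
                k=k_sel, r=r_sel, seed=derive_seed(config.seed, "sweep"),
                n_restarts=config.n_restarts, max_iter=config.max_iter,
                tol=config.tol,
            ))

        stage = "report"
        labels, straddlers = harden(result.membership)
        mem_path = out / "membership.csv"
        pd.DataFrame(
            result.membership.values, index=D.ids,
            columns=[f"cluster_{v}" for v in range(result.membership.k)],
        ).to_csv(mem_path, float_format="%.10f")
        lab_path = out / "labels.tsv"
        pd.DataFrame({
            "id": D.ids, "cluster": labels,
            "max_membership": result.membership.values.max(axis=1),
            "straddler": straddlers,
        }).to_csv(lab_path, sep="\t", index=False)
        sizes = {int(c): int(np.sum(labels == c)) for c in np.unique(labels)}
        report = RunReport(
            selected_k=int(k_sel), selected_r=float(r_sel),
            group_sizes=sizes, n_objects=D.n,
            membership_path=str(mem_path), labels_path=str(lab_path),
            sweep_path=sweep_path, config=config.to_dict(),
            version=__version__, wall_clock_s=round(time.time() - t0, 3),
        )
        with open(out / "report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
        return report
    except ConfigError:
        raise
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed on config {config.fasta!r}: {exc}"
        ) from exc
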