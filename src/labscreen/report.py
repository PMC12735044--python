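"""End-to-end pipeline configuration and deterministic report assembly.

``run_pipeline`` reads a matrix (or a synthetic-panel request), fits the
screening model and emits a provenance-stamped report: matrix digest, config
echo, weights, scores, PCA selection and the agreement flag. The report is
deterministic — same config and inputs give byte-identical JSON (no
timestamps) — so reports can be diffed and round-tripped.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError
from .matrix import IndicatorMatrix
from .model import StrainScreening

__all__ = ["PipelineConfig", "run_pipeline", "report_to_json"]


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for one screening run.

    matrix_path is the matrix-dialect CSV; weights_mode is ``"entropy"`` or
    ``"file"`` (then weights_path points to a two-column indicator,weight
    CSV). epsilon feeds the positivity shift; rounding_digits the display
    rounding; seed is echoed into the report for provenance of synthetic
    inputs.
    """

    matrix_path: "str | None" = None
    orientations: "dict[str, str]" = field(default_factory=dict)
    weights_mode: str = "entropy"
    weights_path: "str | None" = None
    epsilon: float = 1e-6
    rounding_digits: int = 3
    run_pca: bool = True
    seed: "int | None" = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.rounding_digits < 0:
            raise ValidationError("rounding_digits must be >= 0")
        if self.epsilon <= 0:
            raise ValidationError("epsilon must be > 0")
        if self.weights_mode not in ("entropy", "file"):
            raise ValidationError("weights_mode must be 'entropy' or 'file'")
        if self.weights_mode == "file" and not self.weights_path:
            raise ValidationError("weights_mode 'file' needs weights_path")


def _matrix_digest(m: IndicatorMatrix) -> str:
    payload = m.values.to_csv().encode()
    return hashlib.sha256(payload).hexdigest()


def run_pipeline(
    cfg: PipelineConfig, matrix: "IndicatorMatrix | None" = None
) -> dict:
    """Fit the screening model and return the full report dict.

    A pre-built matrix may be passed directly (tests, library use);
    otherwise it is read from ``cfg.matrix_path``.
    """
    if matrix is None:
        if not cfg.matrix_path:
            raise ValidationError("no matrix supplied: set matrix_path")
        matrix = IndicatorMatrix.from_csv(cfg.matrix_path, cfg.orientations)

    weights = None
    if cfg.weights_mode == "file":
        wdf = pd.read_csv(cfg.weights_path)
        if wdf.shape[1] < 2:
            raise ValidationError("weights CSV needs indicator,weight columns")
        weights = pd.Series(
            wdf.iloc[:, 1].astype(float).values, index=wdf.iloc[:, 0].astype(str)
        )

    model = StrainScreening(matrix, epsilon=cfg.epsilon)
    results = model.fit(
        weights=weights, run_pca=cfg.run_pca, digits=cfg.rounding_digits
    )
    report = results.to_report()
    report["matrix_sha256"] = _matrix_digest(matrix)
    report["config"] = {
        "orientations": dict(cfg.orientations),
        "weights_mode": cfg.weights_mode,
        "epsilon": cfg.epsilon,
        "rounding_digits": cfg.rounding_digits,
        "run_pca": cfg.run_pca,
        "seed": cfg.seed,
    }
    return report


def report_to_json(report: dict) -> str:
    """Canonical serialization: sorted keys, fixed separators, trailing
    newline — byte-stable for identical reports."""
    return json.dumps(report, indent=2, sort_keys=True) + "\n"
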