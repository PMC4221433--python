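"""Global min-max normalization of expression matrices, linear or logarithmic.

Both modes rescale the original values (OV) of a whole matrix into [0, 1]
using the global minimum and maximum:

    linear:  NV = (OV - Min) / (Max - Min)
    log:     NV = (log_a OV - log_a Min) / (log_a Max - log_a Min)

Min and Max are taken over *all* cells, never per row; the minimum cell maps
to 0 and the maximum to 1.  The log mode requires every cell (hence Min) to
be strictly positive, and both modes require Max != Min.  Because the log
base cancels in the ratio, the normalized output is independent of ``a``;
the base remains configurable (2 by default, 10 and e as named shortcuts)
so colorbar annotations can state the scale readers expect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ValidationError
from .tabular_io import ExpressionTable

#: Named log-base shortcuts accepted by the CLI and config files.
BASE_SHORTCUTS: dict[str, float] = {"2": 2.0, "10": 10.0, "e": math.e}

DEFAULT_LOG_BASE = 2.0

MODES = ("linear", "log")


def resolve_base(base: str | float) -> float:
    """Turn a base spec ("2", "10", "e" or any positive real != 1) into a float."""
    if isinstance(base, str):
        if base in BASE_SHORTCUTS:
            return BASE_SHORTCUTS[base]
        try:
            base = float(base)
        except ValueError:
            raise ValidationError(
                f"log base must be a positive number or one of "
                f"{sorted(BASE_SHORTCUTS)}, got {base!r}"
            ) from None
    return base


@dataclass(frozen=True)
class NormalizationSpec:
    """How a matrix is mapped to [0, 1].

    Parameters
    ----------
    mode : {"linear", "log"}
        Linear min-max (default) or log min-max scaling.
    base_a : float
        Logarithm base, meaningful only in log mode.  Must be positive and
        != 1.  Default 2; 10 and e are the conventional alternatives.
    """

    mode: str = "linear"
    base_a: float = DEFAULT_LOG_BASE

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not (self.base_a > 0) or self.base_a == 1:
            raise ValidationError(
                f"log base must be > 0 and != 1, got {self.base_a!r}"
            )


@dataclass
class NormalizedMatrix:
    """Matrix of normalized values in [0, 1] plus the Min/Max and spec used."""

    values: np.ndarray
    spec: NormalizationSpec
    ov_min: float
    ov_max: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _extremes(values: np.ndarray) -> tuple[float, float]:
    ov_min = float(values.min())
    ov_max = float(values.max())
    if ov_min == ov_max:
        raise ValidationError(
            f"cannot normalize a constant matrix: the maximum must differ from "
            f"the minimum (all cells equal {ov_min})"
        )
    return ov_min, ov_max


def normalize_linear(table: ExpressionTable) -> NormalizedMatrix:
    """Linear min-max: NV = (OV - Min) / (Max - Min), global over the matrix."""
    ov_min, ov_max = _extremes(table.values)
    nv = (table.values - ov_min) / (ov_max - ov_min)
    return NormalizedMatrix(nv, NormalizationSpec(mode="linear"), ov_min, ov_max)


def normalize_log(
    table: ExpressionTable, spec: NormalizationSpec | None = None
) -> NormalizedMatrix:
    """Log min-max: NV = (log_a OV - log_a Min) / (log_a Max - log_a Min).

    Every cell must be strictly positive; the first offending coordinate is
    reported in the error.  Output is independent of the base.
    """
    if spec is None:
        spec = NormalizationSpec(mode="log")
    elif spec.mode != "log":
        spec = NormalizationSpec(mode="log", base_a=spec.base_a)
    nonpos = np.argwhere(table.values <= 0)
    if nonpos.size:
        i, j = nonpos[0]
        raise DomainError(
            f"log normalization requires all values > 0; cell at row {i + 1}, "
            f"column {j + 1} is {float(table.values[i, j]):g}"
        )
    ov_min, ov_max = _extremes(table.values)
    log_a = math.log(spec.base_a)
    lv = np.log(table.values) / log_a
    lmin = math.log(ov_min) / log_a
    lmax = math.log(ov_max) / log_a
    if lmax == lmin:  # Min and Max so close their logs coincide in float
        raise ValidationError(
            f"cannot log-normalize: Min={ov_min!r} and Max={ov_max!r} are "
            f"indistinguishable on the log scale"
        )
    nv = np.clip((lv - lmin) / (lmax - lmin), 0.0, 1.0)
    return NormalizedMatrix(nv, spec, ov_min, ov_max)


def normalize(table: ExpressionTable, spec: NormalizationSpec) -> NormalizedMatrix:
    """Dispatch on ``spec.mode``."""
    if spec.mode == "linear":
        return normalize_linear(table)
    return normalize_log(table, spec)
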