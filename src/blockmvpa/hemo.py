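"""Hemodynamic response kernel and block-regressor construction."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import special

from .design import BlockSchedule
from .errors import ConfigurationError


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma impulse response.

    h(t) = g(t; peak_delay, peak_dispersion)
           - undershoot_ratio * g(t; undershoot_delay, undershoot_dispersion)

    with g a gamma density. Defaults: 6 s peak, 16 s undershoot, unit
    dispersions, 1/6 undershoot ratio, 32 s support.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    length_seconds: float = 32.0

    def __post_init__(self) -> None:
        if min(self.peak_delay, self.undershoot_delay) <= 0:
            raise ConfigurationError("gamma delays must be positive")
        if min(self.peak_dispersion, self.undershoot_dispersion) <= 0:
            raise ConfigurationError("gamma dispersions must be positive")
        if self.length_seconds <= 0:
            raise ConfigurationError("kernel length must be positive")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Un-normalized double-gamma evaluated at times ``t`` (seconds)."""
        t = np.asarray(t, dtype=float)

        def gamma_pdf(x: np.ndarray, shape: float, scale: float) -> np.ndarray:
            x = np.maximum(x, 0.0) / scale
            with np.errstate(divide="ignore", invalid="ignore"):
                log_pdf = (shape - 1) * np.log(x) - x - special.gammaln(shape)
            out = np.where(x > 0, np.exp(log_pdf), 0.0) / scale
            return out

        peak = gamma_pdf(t, self.peak_delay / self.peak_dispersion, self.peak_dispersion)
        under = gamma_pdf(
            t, self.undershoot_delay / self.undershoot_dispersion, self.undershoot_dispersion
        )
        return peak - self.undershoot_ratio * under


def hrf_kernel(params: HRFParams, tr_seconds: float) -> np.ndarray:
    """Sample the double-gamma response at TR resolution, unit peak.

    The kernel starts at t = 0 (value 0 by construction) and spans
    ``length_seconds``.
    """
    if tr_seconds <= 0:
        raise ConfigurationError("tr_seconds must be positive")
    t = np.arange(0.0, params.length_seconds + 1e-9, tr_seconds)
    kernel = params.evaluate(t)
    peak = kernel.max()
    if peak <= 0:
        raise ConfigurationError("kernel has non-positive peak; check HRF parameters")
    return kernel / peak


def condition_boxcar(schedule: BlockSchedule, conditions: Iterable[str], n_trs: int) -> np.ndarray:
    """0/1 indicator over TRs for blocks of the given conditions."""
    box = np.zeros(n_trs)
    wanted = set([conditions] if isinstance(conditions, str) else conditions)
    for block in schedule.blocks:
        if block.condition in wanted:
            box[block.onset_tr : min(block.end_tr, n_trs)] = 1.0
    return box


def condition_regressors(
    schedule: BlockSchedule,
    regressors: Mapping[str, Sequence[str]],
    n_trs: int,
    hrf: HRFParams,
    tr_seconds: float,
) -> np.ndarray:
    """HRF-convolved boxcar regressors, one column per entry of ``regressors``.

    ``regressors`` maps a regressor name to the block conditions it pools
    (e.g. ``{"faces": ("identity1", "identity2")}``).
    """
    kernel = hrf_kernel(hrf, tr_seconds)
    cols = []
    for conds in regressors.values():
        box = condition_boxcar(schedule, conds, n_trs)
        cols.append(np.convolve(box, kernel)[:n_trs])
    return np.column_stack(cols) if cols else np.zeros((n_trs, 0))
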