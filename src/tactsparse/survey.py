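"""Survey orchestration: wavelet x dimensionality x NMSE-target sweep.

For every requested triple, the quantization-factor search runs once per
recording and the three metrics are arithmetically averaged across the
dataset, producing one table row per triple.  Unconverged and failed cells
are kept in the table with a status flag (silent omission would bias
rankings) but are never ranked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import TABLE_COLUMNS, TactileRecording
from .sparsifier import DEFAULT_TARGETS, SparsificationResult, search_q
from .transforms import WaveletSpec, wavelet_registry

logger = logging.getLogger(__name__)

#: metric -> (column, ascending?) for rankings: sparser and cheaper rank
#: first; higher retained energy ranks first.
_METRICS = {
    "sparsity": ("sparsity", True),
    "nbp": ("bits_per_pixel", True),
    "energy_ratio": ("energy_ratio", False),
}


@dataclass
class SurveyCell:
    """One table row: an aggregated result plus its convergence status."""

    result: SparsificationResult | None
    wavelet_name: str
    transform: str
    dimensionality: int
    target_nmse: float
    status: str  # converged | unconverged | unimplemented | error:<msg>

    def row(self) -> dict:
        r = self.result
        return {
            "wavelet": self.wavelet_name,
            "transform": self.transform,
            "dimensionality": self.dimensionality,
            "target_nmse": self.target_nmse,
            "achieved_nmse": r.achieved_nmse if r else np.nan,
            "Q": r.Q if r else np.nan,
            "sparsity": r.sparsity if r else np.nan,
            "bits_per_pixel": r.bits_per_pixel if r else np.nan,
            "energy_ratio": r.energy_ratio if r else np.nan,
            "iterations": r.iterations if r else 0,
            "n_recordings": r.n_recordings if r else 0,
            "status": self.status,
        }


@dataclass
class SurveyTable:
    """Ranked collection of sparsification results (the survey's main output)."""

    cells: list[SurveyCell]
    dataset_id: str = ""
    denoise_settings: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([c.row() for c in self.cells])
        return df.reindex(columns=TABLE_COLUMNS)

    @property
    def converged(self) -> list[SurveyCell]:
        return [c for c in self.cells if c.status == "converged"]

    def find(self, wavelet: str, dimensionality: int, target: float,
             transform: str = "dwt") -> SurveyCell | None:
        for c in self.cells:
            if (c.wavelet_name == wavelet and c.dimensionality == dimensionality
                    and c.transform == transform
                    and np.isclose(c.target_nmse, target)):
                return c
        return None


def _aggregate(per_recording: list[SparsificationResult]) -> SparsificationResult:
    first = per_recording[0]
    agg = replace(
        first,
        achieved_nmse=float(np.mean([r.achieved_nmse for r in per_recording])),
        Q=float(np.mean([r.Q for r in per_recording])),
        sparsity=float(np.mean([r.sparsity for r in per_recording])),
        bits_per_pixel=float(np.mean([r.bits_per_pixel for r in per_recording])),
        energy_ratio=float(np.mean([r.energy_ratio for r in per_recording])),
        iterations=int(np.max([r.iterations for r in per_recording])),
        converged=all(r.converged for r in per_recording),
        n_recordings=len(per_recording),
    )
    return agg


def run_survey(
    dataset: list[TactileRecording],
    wavelets: list[WaveletSpec | str] | None = None,
    dimensionalities: tuple[int, ...] = (1, 2, 3),
    targets: tuple[float, ...] = DEFAULT_TARGETS,
    include_dct: bool = True,
    tolerance_factor: float = 1e-4,
    max_iterations: int = 60,
    mode: str = "periodization",
    normalization: str = "mean",
    dataset_id: str = "",
) -> SurveyTable:
    """Run the full sweep; deterministic given dataset and configuration.

    ``wavelets`` defaults to the full registry; unimplemented entries become
    table rows flagged ``unimplemented``.  Individual cell failures are
    recorded per cell, never fatal.
    """
    if not dataset:
        raise ValidationError("dataset: empty recording collection")
    if wavelets is None:
        wavelets = list(wavelet_registry())
    specs: list[WaveletSpec | str] = []
    from .transforms import get_wavelet

    for w in wavelets:
        specs.append(get_wavelet(w) if isinstance(w, str) else w)
    candidates: list[tuple[str, str]] = [("dwt", s.name) for s in specs]
    if include_dct:
        candidates.append(("dct", "dct"))

    arrays = [rec.frames.astype(float) for rec in dataset]
    cells: list[SurveyCell] = []
    for kind, name in candidates:
        spec = None if kind == "dct" else next(s for s in specs if s.name == name)
        for dim in dimensionalities:
            for target in targets:
                if spec is not None and not spec.implemented:
                    cells.append(SurveyCell(None, name, kind, dim, target, "unimplemented"))
                    continue
                try:
                    per_rec = [
                        search_q(
                            a, "dct" if kind == "dct" else spec, dim, target,
                            tolerance=tolerance_factor * target,
                            max_iterations=max_iterations,
                            mode=mode, normalization=normalization,
                        )
                        for a in arrays
                    ]
                    agg = _aggregate(per_rec)
                    cells.append(SurveyCell(agg, name, kind, dim, target, agg.status))
                except Exception as exc:  # recorded per-cell, never fatal
                    logger.warning("survey cell (%s, %dD, %g) failed: %s", name, dim, target, exc)
                    cells.append(SurveyCell(None, name, kind, dim, target, f"error:{exc}"))
                logger.info("survey: %s %dD target=%g -> %s", name, dim, target, cells[-1].status)
    return SurveyTable(cells=cells, dataset_id=dataset_id)


def rank_by(table: SurveyTable, dimensionality: int, metric: str, top_k: int = 5,
            transform: str = "dwt", target: float | None = None) -> list[SurveyCell]:
    """Top-k converged cells for one dimensionality, best first.

    Ascending for sparsity and bits per pixel, descending for energy ratio;
    ties broken by wavelet name lexicographically.  ``target`` restricts the
    ranking to one NMSE target (rankings across mixed targets are rarely
    meaningful).
    """
    try:
        column, ascending = _METRICS[metric]
    except KeyError:
        raise ValidationError(
            f"metric: unknown metric {metric!r}; expected one of {sorted(_METRICS)}"
        ) from None
    pool = [
        c for c in table.converged
        if c.dimensionality == dimensionality and c.transform == transform
        and (target is None or np.isclose(c.target_nmse, target))
    ]
    sign = 1.0 if ascending else -1.0
    pool.sort(key=lambda c: (sign * getattr(c.result, column), c.wavelet_name))
    return pool[: max(0, int(top_k))]


def dct_sparsity_ratio(table: SurveyTable, dimensionality: int, target: float) -> float:
    """(DCT sparsity) / (best DWT sparsity) for one dimensionality and target."""
    dct_cell = table.find("dct", dimensionality, target, transform="dct")
    if dct_cell is None or dct_cell.result is None or dct_cell.status != "converged":
        raise ValidationError(
            f"no converged DCT baseline for dimensionality {dimensionality}, target {target}"
        )
    best = rank_by(table, dimensionality, "sparsity", top_k=1, target=target)
    if not best:
        raise ValidationError(
            f"no converged DWT entries at target {target} for dimensionality {dimensionality}"
        )
    return dct_cell.result.sparsity / best[0].result.sparsity
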