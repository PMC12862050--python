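"""Patient cohort generator.

Each patient contributes a matched pair of 13x13 sample grids: one taken
near the tumor core and one from the resection margin.  Cell compositions
are drawn from a mixture of vertex point masses (homogeneous regions) and
interior draws on the 2-simplex, rounded to integer percentages with a
largest-remainder correction.  Raw measurements are generated lazily and
deterministically from per-cell child seeds, so a cohort of any size can
be streamed without holding the decay stacks in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from ..types import DRMeasurement, TISSUES, TRFMeasurement, TissueComposition
from .library import TissueLibrary, composition_to_optics
from .simulate import DRSimConfig, TRFSimConfig, simulate_dr, simulate_trf

__all__ = ["GridMixConfig", "CohortConfig", "SampleGrid", "Cohort", "ROIRef",
           "generate_cohort", "round_to_percent"]

GRID_SIZE = 13
SAMPLE_KINDS = ("tumor_core", "margin_normal")


def round_to_percent(fractions: np.ndarray) -> tuple[int, int, int]:
    """Round nonnegative fractions summing to 1 to integer percents summing
    to 100 using the largest-remainder method (ties broken by index)."""
    x = np.asarray(fractions, float) * 100.0
    if x.min() < -1e-9 or abs(x.sum() - 100.0) > 1e-6:
        raise ValueError("fractions must be nonnegative and sum to 1")
    base = np.floor(x).astype(int)
    short = 100 - int(base.sum())
    remainders = x - base
    order = np.argsort(-remainders, kind="stable")
    base[order[:short]] += 1
    return tuple(int(v) for v in base)


@dataclass(frozen=True)
class GridMixConfig:
    """Composition mixture for one sample kind.

    ``vertex_weights`` are homogeneous-draw probabilities over
    (tumor, fibroglandular, adipose); ``p_tumor_het`` is the probability
    that a heterogeneous cell contains any tumor.
    """

    vertex_weights: tuple[float, float, float]
    p_tumor_het: float
    alpha_tumor: tuple[float, float, float] = (1.4, 1.0, 1.2)
    alpha_normal: tuple[float, float] = (1.2, 1.4)


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 20
    p_homogeneous: float = 0.33
    core: GridMixConfig = GridMixConfig(vertex_weights=(0.55, 0.05, 0.40), p_tumor_het=0.65)
    margin: GridMixConfig = GridMixConfig(vertex_weights=(0.08, 0.12, 0.80), p_tumor_het=0.17)
    min_tumor_pct: int = 1        # floor on p_tumor when a heterogeneous draw has tumor
    occupancy: float = 1.0        # fraction of in-holder cells that carry tissue
    contrast: float = 1.0         # tumor-vs-normal optical contrast (library blend)
    trf: TRFSimConfig = field(default_factory=lambda: TRFSimConfig(sigma=0.01))
    dr: DRSimConfig = field(default_factory=lambda: DRSimConfig(sigma=0.005))

    def mix_for(self, sample_kind: str) -> GridMixConfig:
        return self.core if sample_kind == "tumor_core" else self.margin


def _holder_mask() -> np.ndarray:
    """Cells inside the circular 12.7 mm sample holder on the 13x13 grid."""
    idx = np.arange(GRID_SIZE) - (GRID_SIZE - 1) / 2.0
    rr, cc = np.meshgrid(idx, idx, indexing="ij")
    return np.hypot(rr, cc) <= 12.7 / 2.0


def _draw_composition(rng: np.random.Generator, cfg: CohortConfig,
                      mix: GridMixConfig) -> TissueComposition:
    if rng.random() < cfg.p_homogeneous:
        tissue = rng.choice(3, p=np.asarray(mix.vertex_weights) / sum(mix.vertex_weights))
        pct = [0, 0, 0]
        pct[tissue] = 100
        return TissueComposition(*pct)
    for _ in range(100):
        if rng.random() < mix.p_tumor_het:
            frac = rng.dirichlet(mix.alpha_tumor)
            if frac[0] * 100 < cfg.min_tumor_pct:
                continue
        else:
            fa = rng.dirichlet(mix.alpha_normal)
            frac = np.array([0.0, fa[0], fa[1]])
        pct = round_to_percent(frac)
        if max(pct) < 100:  # keep the draw genuinely heterogeneous after rounding
            return TissueComposition(*pct)
    raise RuntimeError("failed to draw a heterogeneous composition")  # pragma: no cover


@dataclass(frozen=True)
class ROIRef:
    """Identifies one measured cell within a cohort."""

    patient_id: str
    patient_index: int
    sample_kind: str
    row: int
    col: int
    composition: TissueComposition


@dataclass
class SampleGrid:
    patient_id: str
    sample_kind: str
    cells: dict[tuple[int, int], TissueComposition]  # absent key = empty cell

    shape = (GRID_SIZE, GRID_SIZE)


@dataclass
class Cohort:
    config: CohortConfig
    seed: int
    library: TissueLibrary
    patients: list[dict[str, SampleGrid]]  # sample_kind -> grid

    def iter_rois(self) -> Iterator[ROIRef]:
        for p_idx, grids in enumerate(self.patients):
            pid = f"P{p_idx + 1:03d}"
            for kind in SAMPLE_KINDS:
                for (r, c), comp in sorted(grids[kind].cells.items()):
                    yield ROIRef(pid, p_idx, kind, r, c, comp)

    def annotations(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": roi.patient_id,
                "sample": roi.sample_kind,
                "row": roi.row,
                "col": roi.col,
                "p_tumor": roi.composition.p_tumor,
                "p_fibro": roi.composition.p_fibro,
                "p_adipose": roi.composition.p_adipose,
                "label": roi.composition.label,
            }
            for roi in self.iter_rois()
        ]
        return pd.DataFrame(rows)

    def measure(self, roi: ROIRef) -> tuple[TRFMeasurement, DRMeasurement]:
        """Deterministic raw measurements for one cell.

        Child RNGs are spawned from (cohort seed, patient, sample, row, col)
        so any cell can be re-simulated independently and bit-identically.
        """
        kind_idx = SAMPLE_KINDS.index(roi.sample_kind)
        gt = composition_to_optics(roi.composition, self.library)
        ss_trf = np.random.SeedSequence(self.seed, spawn_key=(1, roi.patient_index, kind_idx, roi.row, roi.col))
        ss_dr = np.random.SeedSequence(self.seed, spawn_key=(2, roi.patient_index, kind_idx, roi.row, roi.col))
        trf = simulate_trf(gt, self.config.trf, rng=np.random.default_rng(ss_trf))
        dr = simulate_dr(gt, self.config.dr, rng=np.random.default_rng(ss_dr))
        return trf, dr

    def iter_measurements(self) -> Iterator[tuple[ROIRef, TRFMeasurement, DRMeasurement]]:
        for roi in self.iter_rois():
            trf, dr = self.measure(roi)
            yield roi, trf, dr


def generate_cohort(n_patients: int | None = None, cfg: CohortConfig | None = None,
                    seed: int = 0, library: TissueLibrary | None = None) -> Cohort:
    """Generate the full cohort of matched grid pairs (annotations only;
    measurements are produced lazily by :meth:`Cohort.measure`)."""
    cfg = cfg or CohortConfig()
    if n_patients is not None:
        cfg = replace(cfg, n_patients=n_patients)
    if cfg.n_patients < 2:
        raise ValueError("need at least 2 patients")
    library = library or TissueLibrary.default()
    if cfg.contrast != 1.0:
        library = library.with_contrast(cfg.contrast)

    mask = _holder_mask()
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    patients = []
    for p_idx in range(cfg.n_patients):
        pid = f"P{p_idx + 1:03d}"
        grids = {}
        for kind in SAMPLE_KINDS:
            mix = cfg.mix_for(kind)
            cells = {}
            for r in range(GRID_SIZE):
                for c in range(GRID_SIZE):
                    if not mask[r, c]:
                        continue
                    if cfg.occupancy < 1.0 and rng.random() >= cfg.occupancy:
                        continue
                    cells[(r, c)] = _draw_composition(rng, cfg, mix)
            grids[kind] = SampleGrid(pid, kind, cells)
        patients.append(grids)
    return Cohort(cfg, seed, library, patients)
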