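"""Synthetic patient generator: tapered aortic area profiles with fusiform bulges.

Real inputs to the detectors are per-slice aortic lumen pixel counts from a
tracked CTA segmentation.  Their gross structure is simple: a slowly
tapering cross-sectional area from the thoracic aorta down to the iliac
bifurcation, multiplicative measurement noise, and — in aneurysmal patients
— a fusiform bulge where the area rises well above the local baseline over
tens of slices.  A segmentation model trained only on normal anatomy
instead *drops out* over the aneurysm, collapsing counts to zero there;
``dropout_mode`` emulates that failure signature so the screening classifier
can be exercised.

The generator is deterministic given a :class:`CohortSpec` (including its
seed); per-patient streams are derived counter-style from the cohort seed so
patient ``i`` is identical regardless of cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .signal_extraction import write_signal_table
from .types import AreaSignal, BoundaryInterval, MaskStack

__all__ = [
    "CohortSpec",
    "SyntheticPatient",
    "bulge_envelope",
    "simulate_patient",
    "simulate_cohort",
    "rasterize_patient",
    "write_cohort",
    "read_manifest",
]

_SHAPES = ("plateau", "gaussian", "asymmetric")

#: margin of bulge-free slices kept at both ends of the scan, so detectors
#: always have a normal baseline to anchor on
EDGE_MARGIN = 10


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults describe the regime the detectors are designed for: scans of
    120-200 axial slices, thoracic-end lumen areas of 300-600 pixels, a 15%
    linear taper to the bifurcation, fusiform bulges 20-60 slices long that
    peak at 1.5-3.5x the local baseline, and 3% multiplicative noise.
    """

    n_patients: int = 60
    n_slices_range: tuple[int, int] = (120, 200)
    base_count_range: tuple[float, float] = (300.0, 600.0)
    taper_fraction: float = 0.15
    aneurysm_prob: float = 1.0
    peak_ratio_range: tuple[float, float] = (1.5, 3.5)
    aneurysm_len_range: tuple[int, int] = (20, 60)
    bulge_shape: str = "plateau"
    noise_cv: float = 0.03
    dropout_mode: bool = False
    model_bifurcation: bool = False
    bifurcation_drop: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_slices_range", "base_count_range",
                     "peak_ratio_range", "aneurysm_len_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered (min, max)")
        if self.peak_ratio_range[0] <= 1:
            raise ValueError("peak_ratio_range minimum must exceed 1")
        if not 0 <= self.taper_fraction <= 1:
            raise ValueError("taper_fraction must lie in [0, 1]")
        if not 0 <= self.aneurysm_prob <= 1:
            raise ValueError("aneurysm_prob must lie in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")
        if not 0 < self.bifurcation_drop <= 1:
            raise ValueError("bifurcation_drop must lie in (0, 1]")
        if self.bulge_shape not in _SHAPES:
            raise ValueError(f"bulge_shape must be one of {_SHAPES}")


@dataclass
class SyntheticPatient:
    signal: AreaSignal
    truth: Optional[BoundaryInterval]
    has_aneurysm: bool
    params_used: dict = field(default_factory=dict)


def bulge_envelope(length: int, peak_ratio: float, shape: str) -> np.ndarray:
    """Multiplicative envelope of a fusiform bulge over ``length`` slices.

    Every slice of the bulge support lies strictly above 1 (the virtual
    envelope anchors of 1 sit one slice outside the support), so noise-free
    counts inside the truth interval strictly exceed the tapered baseline
    and counts outside equal it exactly.
    """
    if length < 1:
        raise ValueError("bulge length must be >= 1")
    amp = peak_ratio - 1.0
    k = np.arange(length, dtype=float)
    if shape == "gaussian":
        c = (length - 1) / 2.0
        sigma = max(length / 6.0, 0.5)
        return 1.0 + amp * np.exp(-0.5 * ((k - c) / sigma) ** 2)

    if shape == "plateau":
        r_up = r_down = min(5, max(1, (length - 1) // 2))
    elif shape == "asymmetric":
        r_up = min(3, max(1, (length - 1) // 2))
        r_down = min(8, max(1, (length - 1) // 2))
    else:
        raise ValueError(f"unknown bulge shape {shape!r}")

    env = np.full(length, peak_ratio, dtype=float)
    # raised-cosine ramps; phase (k+1)/(r+1) keeps the interval interior
    # strictly above baseline
    up = 1.0 + amp * (1 - np.cos(np.pi * (k[:r_up] + 1) / (r_up + 1))) / 2
    down = 1.0 + amp * (1 - np.cos(np.pi * (k[:r_down] + 1) / (r_down + 1))) / 2
    env[:r_up] = np.minimum(env[:r_up], up)
    env[length - r_down:] = np.minimum(env[length - r_down:], down[::-1])
    return env


def _noise_factors(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(n)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=n)


def simulate_patient(
    spec: CohortSpec,
    rng: np.random.Generator,
    patient_id: str = "P0000",
    force_interval: Optional[BoundaryInterval] = None,
) -> SyntheticPatient:
    """Draw one synthetic patient from ``spec`` using the supplied stream.

    ``force_interval`` pins the bulge support (used by tests and worked
    examples); all other parameters are sampled as usual.
    """
    n = int(rng.integers(spec.n_slices_range[0], spec.n_slices_range[1] + 1))
    base = float(rng.uniform(*spec.base_count_range))
    has_aneurysm = bool(rng.random() < spec.aneurysm_prob)

    i = np.arange(n, dtype=float)
    taper = 1.0 - spec.taper_fraction * (i / (n - 1) if n > 1 else i)
    profile = base * taper

    truth: Optional[BoundaryInterval] = None
    peak = None
    if has_aneurysm:
        if force_interval is not None:
            truth = force_interval
            length = len(truth)
        else:
            max_len = n - 2 * EDGE_MARGIN
            if spec.aneurysm_len_range[0] >= max_len:
                raise ValueError(
                    f"aneurysm_len_range {spec.aneurysm_len_range} does not fit "
                    f"a scan of {n} slices with {EDGE_MARGIN}-slice margins"
                )
            hi = min(spec.aneurysm_len_range[1], max_len - 1)
            length = int(rng.integers(spec.aneurysm_len_range[0], hi + 1))
            start = int(rng.integers(EDGE_MARGIN, n - length - EDGE_MARGIN + 1))
            truth = BoundaryInterval(start, start + length - 1)
        truth.validate_for(n)
        peak = float(rng.uniform(*spec.peak_ratio_range))
        profile[truth.start:truth.end + 1] *= bulge_envelope(
            length, peak, spec.bulge_shape
        )

    if spec.model_bifurcation:
        bif = int(0.9 * n)
        profile[bif:] *= spec.bifurcation_drop

    profile = profile * _noise_factors(rng, n, spec.noise_cv)
    counts = np.maximum(np.round(profile), 0).astype(np.int64)
    if has_aneurysm and spec.dropout_mode:
        counts[truth.start:truth.end + 1] = 0

    params = {"n": n, "base": base, "peak_ratio": peak,
              "shape": spec.bulge_shape if has_aneurysm else None}
    return SyntheticPatient(
        signal=AreaSignal(patient_id=patient_id, counts=counts),
        truth=truth,
        has_aneurysm=has_aneurysm,
        params_used=params,
    )


def patient_rng(cohort_seed: int, index: int) -> np.random.Generator:
    """Counter-based per-patient stream: independent of cohort size."""
    return np.random.default_rng(np.random.SeedSequence((cohort_seed, index)))


def simulate_cohort(spec: CohortSpec) -> list[SyntheticPatient]:
    """Generate ``spec.n_patients`` independent synthetic patients."""
    cohort = []
    for i in range(spec.n_patients):
        cohort.append(
            simulate_patient(spec, patient_rng(spec.seed, i), patient_id=f"P{i:04d}")
        )
    return cohort


def rasterize_patient(
    patient: SyntheticPatient, shape: tuple[int, int] = (128, 128)
) -> MaskStack:
    """Render each slice as a centered filled disc with the slice's exact count.

    Pixels are ranked by distance from the slice center (ties broken
    lexicographically) and exactly ``counts[i]`` nearest pixels are set, so
    a load -> extract round trip reproduces the generator's counts exactly.
    """
    h, w = shape
    area = h * w
    counts = patient.signal.counts
    if counts.max(initial=0) > area:
        raise ValueError(
            f"count {counts.max()} exceeds slice area {area} for shape {shape}"
        )
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    order = np.lexsort((xx.ravel(), yy.ravel(), d2.ravel()))
    stack = np.zeros((counts.size, h, w), dtype=np.uint8)
    flat = stack.reshape(counts.size, -1)
    for i, c in enumerate(counts):
        flat[i, order[:c]] = 1
    return MaskStack(patient_id=patient.signal.patient_id, slices=stack)


def write_cohort(
    cohort: list[SyntheticPatient],
    out_dir: str | Path,
    masks: bool = False,
    mask_shape: tuple[int, int] = (128, 128),
) -> Path:
    """Write per-patient signal CSVs plus a cohort manifest CSV.

    Returns the manifest path.  With ``masks=True`` also writes one
    multi-page TIFF mask stack per patient.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in cohort:
        write_signal_table(p.signal, out_dir / f"{p.signal.patient_id}.csv")
        if masks:
            stack = rasterize_patient(p, mask_shape)
            tifffile.imwrite(
                out_dir / f"{p.signal.patient_id}.tif", stack.slices
            )
        rows.append({
            "patient_id": p.signal.patient_id,
            "n_slices": p.signal.n,
            "has_aneurysm": int(p.has_aneurysm),
            "start": p.truth.start if p.truth else -1,
            "end": p.truth.end if p.truth else -1,
        })
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"patient_id", "n_slices", "has_aneurysm", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    return df
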