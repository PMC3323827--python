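"""Synthetic multi-run GCxGC peak tables with known ground truth.

The generator draws a master metabolite list (2-D retention times, sparse
mass spectra, unique CAS-like keys) and emits per-run peak tables that
emulate the failure modes real ChromaTOF exports exhibit:

* monotone RT warps per run — *homogeneous* runs share the acquisition
  configuration and differ only by small jitter; *heterogeneous* runs get
  distinct affine warps per dimension, emulating different temperature
  gradients;
* multiplicative log-normal spectral noise, renormalized to constant total
  intensity so spectral angles stay well defined;
* within-run peak splitting (duplicate entries of one metabolite, the true
  entry keeping the maximum area) to exercise merging;
* peak dropout; and
* compound-key misassignment at a configurable rate (software
  identification is only ~80% accurate in practice). Label errors never
  touch RTs or spectra, so gold-standard discordance in tests is
  attributable solely to label noise.

All randomness flows through ``numpy.random.default_rng`` (PCG64); a fixed
seed reproduces output exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .peaks import Peak, PeakTable, Spectrum

__all__ = [
    "SimConfig",
    "DimensionWarp",
    "homogeneous_config",
    "heterogeneous_config",
    "generate_master",
    "generate_runs",
    "simulate_dataset",
]


@dataclass(frozen=True)
class DimensionWarp:
    """Affine RT warp rt' = a * rt + c plus Gaussian jitter (per dimension)."""

    a: float = 1.0
    c: float = 0.0
    jitter_sd: float = 0.0


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults emulate a standards-mixture experiment: ~100 metabolites over
    realistic GCxGC RT ranges (first dimension in minutes, second in
    seconds), sparse unit-mass spectra, mild multiplicative spectral noise,
    a few percent dropout and splitting, and a 20% compound-key
    misassignment rate matching typical software identification accuracy.
    """

    n_metabolites: int = 100
    n_runs: int = 3
    rt1_range: tuple[float, float] = (10.0, 60.0)  # minutes
    rt2_range: tuple[float, float] = (1.0, 5.0)  # seconds
    #: per-run warps, one (dim1, dim2) tuple per run; None = identity + jitter
    warps: Optional[Sequence[tuple[DimensionWarp, DimensionWarp]]] = None
    jitter_sd1: float = 0.02  # minutes, used when warps is None
    jitter_sd2: float = 0.01  # seconds
    spectrum_channels: int = 120  # unit-mass channels starting at m/z 50
    spectrum_sparsity: float = 0.15  # fraction of nonzero channels
    min_pairwise_angle: float = 25.0  # degrees, identifiability floor
    noise_sd: float = 0.1  # log-normal sigma of multiplicative spectral noise
    area_noise_sd: float = 0.1  # log-normal sigma of run-to-run area variation
    dropout_rate: float = 0.05
    split_rate: float = 0.1
    label_error_rate: float = 0.2
    seed: int = 0

    def __post_init__(self):
        for name in ("spectrum_sparsity", "dropout_rate", "split_rate", "label_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        if self.rt1_range[0] <= 0 or self.rt1_range[1] <= self.rt1_range[0]:
            raise ParameterError("rt1_range must be positive and increasing")
        if self.rt2_range[0] <= 0 or self.rt2_range[1] <= self.rt2_range[0]:
            raise ParameterError("rt2_range must be positive and increasing")
        if self.n_metabolites < 2:
            raise ParameterError("need at least two metabolites")


def homogeneous_config(**overrides) -> SimConfig:
    """Runs sharing one acquisition configuration: identity warps, jitter only."""
    cfg = SimConfig(**{"label_error_rate": 0.2, **overrides})
    warps = [
        (
            DimensionWarp(1.0, 0.0, cfg.jitter_sd1),
            DimensionWarp(1.0, 0.0, cfg.jitter_sd2),
        )
        for _ in range(cfg.n_runs)
    ]
    return replace(cfg, warps=warps)


def heterogeneous_config(**overrides) -> SimConfig:
    """Distinct affine warps per run, emulating different temperature gradients."""
    cfg = SimConfig(**{"label_error_rate": 0.2, **overrides})
    # deterministic spread of scales/offsets around identity
    n = cfg.n_runs
    a1 = np.linspace(0.85, 1.15, n)
    c1 = np.linspace(-2.0, 2.0, n)  # minutes
    a2 = np.linspace(0.92, 1.08, n)
    c2 = np.linspace(-0.15, 0.15, n)  # seconds
    warps = [
        (
            DimensionWarp(float(a1[i]), float(c1[i]), cfg.jitter_sd1),
            DimensionWarp(float(a2[i]), float(c2[i]), cfg.jitter_sd2),
        )
        for i in range(n)
    ]
    return replace(cfg, warps=warps)


def _synthetic_cas(i: int) -> str:
    return f"{100000 + i}-{i % 100:02d}-{i % 10}"


def generate_master(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> PeakTable:
    """Draw the master metabolite list: RTs, spectra and unique keys.

    Spectra are sparse nonnegative vectors over unit-mass channels; a
    candidate spectrum is redrawn until its angle to every previous master
    spectrum exceeds ``min_pairwise_angle`` (identifiability floor), so no
    two master metabolites are spectrally confusable by construction.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_metabolites
    rt1 = rng.uniform(*config.rt1_range, size=n)
    rt2 = rng.uniform(*config.rt2_range, size=n)
    k = max(2, int(round(config.spectrum_sparsity * config.spectrum_channels)))
    k = min(k, config.spectrum_channels)
    mz_base = 50
    dense: list[np.ndarray] = []
    for i in range(n):
        for _attempt in range(200):
            support = rng.choice(config.spectrum_channels, size=k, replace=False)
            vec = np.zeros(config.spectrum_channels)
            vec[support] = rng.lognormal(mean=0.0, sigma=1.0, size=k)
            if _min_angle_ok(vec, dense, config.min_pairwise_angle):
                break
        else:
            raise ParameterError(
                "could not draw spectra satisfying the pairwise-angle floor; "
                "lower min_pairwise_angle or sparsity"
            )
        dense.append(vec)
    peaks = []
    for i in range(n):
        vec = dense[i]
        nz = np.flatnonzero(vec)
        spec = Spectrum(mz=(mz_base + nz).astype(float), intensity=vec[nz] * 999.0 / vec.max())
        area = float(rng.lognormal(mean=10.0, sigma=1.0))
        peaks.append(
            Peak(
                peak_id=f"M{i:04d}",
                run_id="master",
                rt1=float(rt1[i]),
                rt2=float(rt2[i]),
                area=area,
                spectrum=spec,
                name=f"metabolite_{i:04d}",
                cas=_synthetic_cas(i),
            )
        )
    return PeakTable("master", peaks)


def _min_angle_ok(vec: np.ndarray, others: list[np.ndarray], floor_deg: float) -> bool:
    if not others:
        return True
    m = np.stack(others)
    cos = (m @ vec) / (np.linalg.norm(m, axis=1) * np.linalg.norm(vec))
    ang = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
    return bool(ang.min() > floor_deg)


def _noisy_spectrum(spec: Spectrum, sigma: float, rng: np.random.Generator) -> Spectrum:
    if sigma <= 0:
        return spec
    noise = rng.lognormal(mean=0.0, sigma=sigma, size=spec.intensity.size)
    inten = spec.intensity * noise
    inten *= spec.intensity.sum() / inten.sum()  # constant total intensity
    return Spectrum(mz=spec.mz.copy(), intensity=inten)


def generate_runs(
    master: PeakTable,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[PeakTable], pd.DataFrame]:
    """Emit per-run peak tables plus a ground-truth table.

    The ground truth records, for every generated peak: its run, master
    metabolite, the master ("true") RTs before warping, whether its
    compound key is correct, and whether it is a split artifact. The
    correspondence classes are the groups of non-split peaks sharing a
    metabolite id.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    warps = config.warps
    if warps is None:
        warps = [
            (
                DimensionWarp(1.0, 0.0, config.jitter_sd1),
                DimensionWarp(1.0, 0.0, config.jitter_sd2),
            )
            for _ in range(config.n_runs)
        ]
    if len(warps) != config.n_runs:
        raise ParameterError("need one warp pair per run")
    all_keys = [(p.cas, p.name) for p in master]
    runs: list[PeakTable] = []
    truth_rows = []
    for r in range(config.n_runs):
        w1, w2 = warps[r]
        rid = f"run{r:02d}"
        peaks: list[Peak] = []
        counter = 0
        for m in master:
            if rng.random() < config.dropout_rate:
                continue
            rt1 = w1.a * m.rt1 + w1.c + rng.normal(0.0, w1.jitter_sd)
            rt2 = w2.a * m.rt2 + w2.c + rng.normal(0.0, w2.jitter_sd)
            rt1 = max(rt1, 1e-3)
            rt2 = max(rt2, 1e-3)
            cas, name = m.cas, m.name
            label_ok = True
            # draw unconditionally so the RNG stream (hence RTs and spectra)
            # is identical across label_error_rate settings at a fixed seed
            u_label = rng.random()
            wrong = int(rng.integers(0, len(all_keys)))
            if u_label < config.label_error_rate and all_keys[wrong][0] != m.cas:
                cas, name = all_keys[wrong]
                label_ok = False
            spec = _noisy_spectrum(m.spectrum, config.noise_sd, rng)
            pid = f"{rid}:{counter:04d}"
            counter += 1
            peaks.append(
                Peak(
                    peak_id=pid,
                    run_id=rid,
                    rt1=float(rt1),
                    rt2=float(rt2),
                    area=m.area
                    * (
                        float(rng.lognormal(0.0, config.area_noise_sd))
                        if config.area_noise_sd > 0
                        else 1.0
                    ),
                    spectrum=spec,
                    name=name,
                    cas=cas,
                )
            )
            truth_rows.append(
                dict(
                    peak_id=pid,
                    run_id=rid,
                    metabolite_id=m.peak_id,
                    true_rt1=m.rt1,
                    true_rt2=m.rt2,
                    label_ok=label_ok,
                    is_split=False,
                )
            )
            if rng.random() < config.split_rate:
                # split artifact: same spectrum, slightly shifted rt2,
                # strictly smaller area so merging keeps the true entry
                sp_id = f"{rid}:{counter:04d}"
                counter += 1
                peaks.append(
                    Peak(
                        peak_id=sp_id,
                        run_id=rid,
                        rt1=float(rt1),
                        rt2=float(max(rt2 + rng.normal(0.0, 0.05), 1e-3)),
                        area=peaks[-1].area * float(rng.uniform(0.2, 0.8)),
                        spectrum=_noisy_spectrum(m.spectrum, config.noise_sd, rng),
                        name=name,
                        cas=cas,
                    )
                )
                truth_rows.append(
                    dict(
                        peak_id=sp_id,
                        run_id=rid,
                        metabolite_id=m.peak_id,
                        true_rt1=m.rt1,
                        true_rt2=m.rt2,
                        label_ok=label_ok,
                        is_split=True,
                    )
                )
        runs.append(PeakTable(rid, peaks))
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "peak_id",
            "run_id",
            "metabolite_id",
            "true_rt1",
            "true_rt2",
            "label_ok",
            "is_split",
        ],
    )
    return runs, truth


def simulate_dataset(
    config: SimConfig,
) -> tuple[list[PeakTable], pd.DataFrame, PeakTable]:
    """Generate master + runs + ground truth from one config (one seed)."""
    rng = np.random.default_rng(config.seed)
    master = generate_master(config, rng)
    runs, truth = generate_runs(master, config, rng)
    return runs, truth, master
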