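"""Synthetic data generators with recorded ground truth.

Every generator is deterministic given its seed and returns the observable
object together with a ground-truth record, so estimator tests can consume
the observables and score against the truth.  The defaults emulate the study
system: a 99,378 bp conjugative plasmid whose accessory (AMR) region spans
coordinates 5,700-41,300, sequenced clones carrying mixtures of full-length
and streamlined (AMR-deleted) copies, 1 h mass-action conjugation assays
read out by plating, and 24 h plate-reader growth curves sampled every
5 minutes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .assays import ConjugationCounts, GrowthCurve, density_from_plate
from .coverage import CoverageProfile
from .model import Trajectory

__all__ = [
    "MixtureSpec",
    "AssaySpec",
    "simulate_coverage",
    "simulate_allele_counts",
    "simulate_conjugation",
    "simulate_growth_curve",
    "observables_from_trajectory",
    "write_depth_tsv",
    "write_plate_counts_csv",
    "write_od_csv",
]


@dataclass(frozen=True)
class MixtureSpec:
    """A clone's plasmid content and sequencing conditions.

    ``n_full`` and ``n_streamlined`` are copies per chromosome; expected
    depth per base is ``chrom_depth * (n_full + n_streamlined)`` on the
    backbone and ``chrom_depth * n_full`` inside the deletion.
    ``overdispersion`` scales the variance/mean ratio (1 = pure Poisson,
    >1 = negative binomial).
    """

    length: int = 99_378
    deletion: tuple[int, int] = (5700, 41_300)  # 1-based inclusive
    n_full: float = 1.0
    n_streamlined: float = 9.0
    chrom_depth: float = 100.0
    overdispersion: float = 1.0
    boundary_blur: int = 0  # bases of linear ramp at each deletion edge
    seed: int | None = None

    def __post_init__(self) -> None:
        start, end = self.deletion
        if not (1 <= start < end <= self.length):
            raise ValueError("deletion must lie within the plasmid")
        if self.n_full < 0 or self.n_streamlined < 0:
            raise ValueError("copy numbers must be >= 0")
        if self.chrom_depth <= 0:
            raise ValueError("chromosome depth must be > 0")
        if self.overdispersion < 1.0:
            raise ValueError("overdispersion must be >= 1")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def expected_depth(spec: MixtureSpec) -> np.ndarray:
    """Per-base expected depth implied by the mixture spec."""
    start, end = spec.deletion
    inside = np.zeros(spec.length, dtype=bool)
    inside[start - 1 : end] = True
    copies = np.where(
        inside, spec.n_full, spec.n_full + spec.n_streamlined
    ).astype(float)
    if spec.boundary_blur > 0:
        b = spec.boundary_blur
        ramp = np.linspace(0.0, 1.0, 2 * b + 1)
        lo, hi = spec.n_full, spec.n_full + spec.n_streamlined
        for edge, direction in ((start - 1, -1), (end, +1)):
            idx = np.arange(edge - b, edge + b + 1)
            ok = (idx >= 0) & (idx < spec.length)
            frac = ramp if direction == +1 else ramp[::-1]
            copies[idx[ok]] = lo + (hi - lo) * frac[ok]
    return spec.chrom_depth * copies


def simulate_coverage(
    spec: MixtureSpec, rng: np.random.Generator | None = None
) -> tuple[CoverageProfile, dict]:
    """Draw a per-base depth profile for a full-length/streamlined mixture.

    Depth is Poisson around the expected depth (negative binomial when
    ``overdispersion > 1``, with variance ``overdispersion * mean``).
    Returns the profile plus a ground-truth record.
    """
    rng = _rng(rng if rng is not None else spec.seed)
    mu = expected_depth(spec)
    if spec.overdispersion == 1.0:
        depth = rng.poisson(mu).astype(float)
    else:
        d = spec.overdispersion
        depth = np.zeros(spec.length)
        pos = mu > 0
        n = mu[pos] / (d - 1.0)
        depth[pos] = rng.negative_binomial(n, 1.0 / d).astype(float)
    profile = CoverageProfile(
        name="synthetic_plasmid",
        length=spec.length,
        depth=depth,
        chrom_mean=spec.chrom_depth,
    )
    truth = {
        "n_full": spec.n_full,
        "n_streamlined": spec.n_streamlined,
        "deletion": spec.deletion,
        "chrom_depth": spec.chrom_depth,
        "streamlined_fraction": (
            spec.n_streamlined / (spec.n_full + spec.n_streamlined)
            if spec.n_full + spec.n_streamlined > 0
            else 0.0
        ),
    }
    return profile, truth


def simulate_allele_counts(
    depth: int,
    streamlined_fraction: float,
    rng: np.random.Generator | int | None = None,
) -> tuple[int, int]:
    """Binomial read counts at a backbone locus: (mutant, ancestral).

    Mutant (streamlined-linked, e.g. ``copA*``) reads are
    ``Binomial(depth, streamlined_fraction)``.
    """
    if not 0.0 <= streamlined_fraction <= 1.0:
        raise ValueError("streamlined fraction must be in [0, 1]")
    rng = _rng(rng)
    mutant = int(rng.binomial(depth, streamlined_fraction))
    return mutant, depth - mutant


@dataclass(frozen=True)
class AssaySpec:
    """A mass-action conjugation assay with plating read-out.

    Growth during the short assay defaults to zero (cells freshly diluted
    into pre-warmed medium are still lagging over 1 h); transconjugants may
    themselves conjugate (second-order term, negligible at short times).
    Dilutions are chosen so plates carry countable (~100) colonies at the
    default densities.
    """

    gamma_true: float = 1e-12  # mL/cell/h
    donor0: float = 1e8  # cells/mL
    recipient0: float = 1e8
    duration_h: float = 1.0
    growth_rate: float = 0.0  # per hour, applied to all populations
    transconjugant_conjugation: bool = True
    donor_dilution: float = 1e5
    recipient_dilution: float = 1e5
    transconjugant_dilution: float = 10.0
    volume_ml: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.gamma_true < 0:
            raise ValueError("transfer rate must be >= 0")
        if self.donor0 <= 0 or self.recipient0 <= 0:
            raise ValueError("initial densities must be > 0")
        if self.duration_h <= 0:
            raise ValueError("duration must be > 0")


def _plate(density: float, dilution: float, volume_ml: float, rng):
    mean = density * volume_ml / dilution
    colonies = int(rng.poisson(mean))
    return density_from_plate(colonies, dilution, volume_ml)


def simulate_conjugation(
    spec: AssaySpec, rng: np.random.Generator | None = None
) -> tuple[ConjugationCounts, dict]:
    """Integrate donor/recipient/transconjugant dynamics, then plate.

    Dynamics: ``dT/dt = gamma (D + T?) R + psi T`` with mass-action transfer
    from donors (and, optionally, transconjugants), exponential growth at
    ``growth_rate`` for every population, and recipients converting to
    transconjugants.  Plate counts are Poisson around the expected colonies;
    densities are back-calculated exactly as :func:`~plasmidcomp.assays.density_from_plate`
    would from real plates.
    """
    rng = _rng(rng if rng is not None else spec.seed)
    g, psi = spec.gamma_true, spec.growth_rate
    donate_t = 1.0 if spec.transconjugant_conjugation else 0.0

    def rhs(t, y):
        D, R, T = y
        transfer = g * (D + donate_t * T) * R
        return [psi * D, psi * R - transfer, psi * T + transfer]

    sol = solve_ivp(
        rhs,
        (0.0, spec.duration_h),
        [spec.donor0, spec.recipient0, 0.0],
        method="LSODA",
        rtol=1e-10,
        atol=1e-6,
    )
    if not sol.success:
        raise RuntimeError(f"assay integration failed: {sol.message}")
    D_end, R_end, T_end = sol.y[:, -1]

    donor = _plate(D_end, spec.donor_dilution, spec.volume_ml, rng)
    recipient = _plate(R_end, spec.recipient_dilution, spec.volume_ml, rng)
    trans = _plate(T_end, spec.transconjugant_dilution, spec.volume_ml, rng)

    counts = ConjugationCounts(
        donor=donor.value,
        recipient=recipient.value,
        transconjugant=0.0 if trans.censored else trans.value,
        time_h=spec.duration_h,
        detection_limit=0.5 * spec.transconjugant_dilution / spec.volume_ml,
        transconjugant_censored=trans.censored,
    )
    truth = {
        "gamma_true": g,
        "donor_end": D_end,
        "recipient_end": R_end,
        "transconjugant_end": T_end,
    }
    return counts, truth


def simulate_growth_curve(
    mu: float = 0.6,
    lag: float = 1.0,
    K_od: float = 1.0,
    noise_sd: float = 0.005,
    od0: float = 1e-4,
    interval_min: float = 5.0,
    duration_h: float = 24.0,
    blank: float = 0.0,
    noise_floor: float = 0.0,
    well: str = "synthetic",
    rng: np.random.Generator | int | None = None,
) -> tuple[GrowthCurve, dict]:
    """Lagged-logistic OD600 trajectory with Gaussian photometric noise.

    The culture sits at ``od0`` until ``lag`` hours, then grows logistically
    at maximal rate ``mu`` towards ``K_od`` (``K_od=inf`` gives pure
    exponential growth).  ``od0`` defaults to a 10,000-fold dilution of a
    unit-OD overnight culture.  Readings every ``interval_min`` minutes for
    ``duration_h`` hours, offset by ``blank``.

    ``noise_sd`` is proportional photometric noise — the standard deviation
    as a fraction of the reading, the way reader accuracy is specified
    (e.g. 0.005 = 0.5%) and the dominant component over the exponential
    fitting range.  ``noise_floor`` adds an optional absolute (additive)
    component, default off; real readers have a floor of ~0.001-0.003 OD,
    which degrades log-linear fits near the detection limit.
    """
    if mu <= 0:
        raise ValueError("mu must be > 0")
    if od0 <= 0:
        raise ValueError("od0 must be > 0")
    rng = _rng(rng)
    times = np.arange(0.0, duration_h + 1e-9, interval_min / 60.0)
    tt = np.maximum(times - lag, 0.0)
    if np.isinf(K_od):
        od = od0 * np.exp(mu * tt)
    else:
        od = K_od / (1.0 + (K_od / od0 - 1.0) * np.exp(-mu * tt))
    noisy = od.copy()
    if noise_sd > 0:
        noisy = noisy * (1.0 + rng.normal(0.0, noise_sd, times.size))
    if noise_floor > 0:
        noisy = noisy + rng.normal(0.0, noise_floor, times.size)
    curve = GrowthCurve(times=times, od=noisy + blank, blank=blank, well=well)
    truth = {
        "mu": mu,
        "lag": lag,
        "K_od": K_od,
        "od0": od0,
        "noise_sd": noise_sd,
        "noise_floor": noise_floor,
    }
    return curve, truth


def observables_from_trajectory(
    traj: Trajectory,
    sample_times: np.ndarray,
    n_colonies: int | None = None,
    rng: np.random.Generator | int | None = None,
):
    """Daily AMR-carrying fraction implied by a model trajectory.

    The wildtype plasmid is the AMR-marked variant (streamlined = unmarked),
    so the AMR fraction is ``(NW + NWM) / T`` at each sampled time
    (interpolated on the trajectory).  With ``n_colonies``, binomial plating
    noise is added: the observed fraction is ``Binomial(n, p) / n``.
    Returns a DataFrame with columns ``time``, ``amr_fraction`` and, when
    noisy, ``amr_fraction_observed``.
    """
    import pandas as pd

    sample_times = np.asarray(sample_times, dtype=float)
    y = np.vstack(
        [np.interp(sample_times, traj.t, traj.y[i]) for i in range(4)]
    )
    total = y.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, (y[1] + y[3]) / total, 0.0)
    out = pd.DataFrame({"time": sample_times, "amr_fraction": frac})
    if n_colonies is not None:
        rng = _rng(rng)
        k = rng.binomial(n_colonies, np.clip(frac, 0.0, 1.0))
        out["amr_fraction_observed"] = k / n_colonies
    return out


def write_depth_tsv(profile: CoverageProfile, path) -> None:
    """Write the 3-column (reference, position, depth) tab-delimited dialect
    consumed by :func:`~plasmidcomp.coverage.read_depth_table`."""
    import pandas as pd

    pd.DataFrame(
        {
            "reference": profile.name,
            "pos": np.arange(1, profile.length + 1),
            "depth": profile.depth.astype(int)
            if np.allclose(profile.depth, np.round(profile.depth))
            else profile.depth,
        }
    ).to_csv(path, sep="\t", header=False, index=False)


def write_plate_counts_csv(rows, path) -> None:
    """Write tidy plate counts (sample, plate_type, dilution, volume_ml,
    colonies)."""
    import pandas as pd

    pd.DataFrame(
        rows, columns=["sample", "plate_type", "dilution", "volume_ml", "colonies"]
    ).to_csv(path, index=False)


def write_od_csv(curves, path) -> None:
    """Write tidy OD readings (well, time_h, od) for one or more curves."""
    import pandas as pd

    if isinstance(curves, GrowthCurve):
        curves = [curves]
    frames = [
        pd.DataFrame({"well": c.well, "time_h": c.times, "od": c.od})
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
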