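"""Copy-number deconvolution of plasmid variants from sequencing depth.

A clone may carry a mixture of full-length plasmid copies and "streamlined"
copies in which the accessory (antimicrobial-resistance, AMR) region has been
deleted.  Per-base read depth over the plasmid reference then shows two
levels: the backbone is covered by all copies, while the AMR region is
covered only by full-length copies.  Normalising region-mean depths by the
chromosome mean depth turns them into copies per chromosome, from which the
number of full-length and streamlined copies — and the expected frequency of
backbone marker alleles such as ``copA*`` — follow directly.

All coordinates are 1-based inclusive, matching how the reference intervals
are usually reported; the depth-table reader performs no conversion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CoverageProfile",
    "RegionSet",
    "MixtureEstimate",
    "DeletionCall",
    "DEFAULT_REGIONS",
    "read_depth_table",
    "region_mean",
    "relative_coverage",
    "estimate_mixture",
    "copA_consistency",
    "detect_deletion",
    "detect_deletions",
    "clone_report",
]

#: Reference length of the R1-like replicon the default regions refer to.
DEFAULT_REFERENCE_LENGTH = 99_378


@dataclass
class CoverageProfile:
    """Per-base read depth over one reference sequence.

    ``depth[i]`` is the depth at 1-based position ``i + 1``.  ``chrom_mean``
    is the mean depth of reads mapped to the host chromosome, used to express
    plasmid coverage as copies per chromosome.  ``unique_reads`` records
    (without verification) whether depths count uniquely mapped reads only.
    """

    name: str
    length: int
    depth: np.ndarray
    chrom_mean: float | None = None
    unique_reads: bool = True

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.length <= 0:
            raise ValueError("reference length must be > 0")
        if self.depth.shape != (self.length,):
            raise ValueError(
                f"depth array length {self.depth.shape} does not match "
                f"reference length {self.length}"
            )
        if np.any(self.depth < 0):
            raise ValueError("depths must be >= 0")
        if self.chrom_mean is not None and self.chrom_mean <= 0:
            raise ValueError("chromosome mean depth must be > 0")


@dataclass(frozen=True)
class RegionSet:
    """Named sets of 1-based inclusive intervals on a reference."""

    regions: dict[str, tuple[tuple[int, int], ...]]
    reference_length: int = DEFAULT_REFERENCE_LENGTH

    def __post_init__(self) -> None:
        for name, intervals in self.regions.items():
            covered = np.zeros(0)
            seen: list[tuple[int, int]] = []
            for start, end in intervals:
                if not (1 <= start <= end <= self.reference_length):
                    raise ValueError(
                        f"interval ({start}, {end}) of region {name!r} outside "
                        f"[1, {self.reference_length}]"
                    )
                for s2, e2 in seen:
                    if start <= e2 and s2 <= end:
                        raise ValueError(
                            f"overlapping intervals within region {name!r}"
                        )
                seen.append((start, end))

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask (0-based array of reference length) of the region."""
        if name not in self.regions:
            raise KeyError(f"no region named {name!r}")
        m = np.zeros(self.reference_length, dtype=bool)
        for start, end in self.regions[name]:
            m[start - 1 : end] = True
        return m

    @classmethod
    def from_bed(cls, path, reference_length: int = DEFAULT_REFERENCE_LENGTH) -> "RegionSet":
        """Build a region set from a BED file (0-based half-open converted to
        1-based inclusive); the BED name column groups intervals."""
        regions: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError("BED file must have a name column (4 fields)")
                start, end, name = int(fields[1]), int(fields[2]), fields[3]
                regions.setdefault(name, []).append((start + 1, end))
        return cls(
            {k: tuple(v) for k, v in regions.items()},
            reference_length=reference_length,
        )


#: Default backbone / AMR intervals on the 99,378 bp R1-like reference.  The
#: short gaps between them (5571-6199 and 15336-15949) hold repeated IS
#: sequence where unique-read depth is unreliable and are excluded from both.
DEFAULT_REGIONS = RegionSet(
    {
        "backbone": ((1, 5570), (41_387, 99_378)),
        "AMR": ((6200, 15_335), (15_950, 40_664)),
    }
)


@dataclass(frozen=True)
class MixtureEstimate:
    """Inferred full-length / streamlined plasmid copy mixture.

    ``r`` is the relative frequency of the AMR region versus the backbone
    (capped at 1); ``streamlined_fraction = 1 - r`` is also the expected
    frequency of a marker allele carried by every streamlined copy (e.g.
    ``copA*``) among all plasmid copies.
    """

    backbone_rel: float
    amr_rel: float
    n_full: float
    n_streamlined: float
    r: float
    streamlined_fraction: float


@dataclass(frozen=True)
class DeletionCall:
    """A contiguous low-coverage run interpreted as a deletion."""

    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    inside_level: float
    outside_level: float
    threshold: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_depth_table(
    path,
    reference: str | None = None,
    length: int | None = None,
    chrom_mean: float | None = None,
    unique_reads: bool = True,
) -> CoverageProfile:
    """Read a 3-column depth table (reference, 1-based position, depth).

    The dialect is the tab-delimited output of standard depth utilities
    (e.g. ``samtools depth``).  Positions absent from the table get depth 0.
    Files covering several references must be disambiguated with
    ``reference``; ``length`` defaults to the largest position seen.
    """
    try:
        table = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["reference", "pos", "depth"],
            dtype={"reference": str},
        )
    except pd.errors.EmptyDataError:
        raise ValueError(f"no records in depth table {path}") from None
    if table.empty:
        raise ValueError(f"no records in depth table {path}")
    if table[["pos", "depth"]].isna().any().any():
        raise ValueError(f"malformed lines in depth table {path}")
    refs = table["reference"].unique()
    if reference is None:
        if len(refs) > 1:
            raise ValueError(
                f"depth table contains multiple references {sorted(refs)}; "
                "pass reference= to select one"
            )
        reference = refs[0]
    table = table[table["reference"] == reference]
    if table.empty:
        raise ValueError(f"no records for reference {reference!r}")
    pos = table["pos"].to_numpy(dtype=np.int64)
    if np.any(pos < 1):
        raise ValueError("positions must be 1-based (>= 1)")
    if length is None:
        length = int(pos.max())
    elif np.any(pos > length):
        raise ValueError(
            f"positions exceed declared reference length {length}"
        )
    depth = np.zeros(length)
    depth[pos - 1] = table["depth"].to_numpy(dtype=float)
    return CoverageProfile(
        name=reference,
        length=length,
        depth=depth,
        chrom_mean=chrom_mean,
        unique_reads=unique_reads,
    )


def region_mean(
    profile: CoverageProfile, regions: RegionSet | None = None, name: str = "backbone"
) -> float:
    """Arithmetic mean depth over the union of a named region's intervals."""
    regions = regions or DEFAULT_REGIONS
    if regions.reference_length != profile.length:
        raise ValueError(
            f"region set is defined on a {regions.reference_length} bp "
            f"reference but the profile is {profile.length} bp"
        )
    mask = regions.mask(name)
    if not mask.any():
        raise ValueError(f"region {name!r} is empty")
    return float(profile.depth[mask].mean())


def relative_coverage(region_mean_depth: float, chrom_mean: float) -> float:
    """Region depth expressed as copies per chromosome."""
    if chrom_mean <= 0:
        raise ValueError("chromosome mean depth must be > 0")
    if region_mean_depth < 0:
        raise ValueError("region mean depth must be >= 0")
    return region_mean_depth / chrom_mean


def estimate_mixture(backbone_rel: float, amr_rel: float) -> MixtureEstimate:
    """Deconvolve relative coverages into full-length vs streamlined copies.

    Full-length copies cover both regions, streamlined copies only the
    backbone, so ``n_full = amr_rel`` and
    ``n_streamlined = backbone_rel - amr_rel``.  Noise can push ``amr_rel``
    slightly above ``backbone_rel``; the estimate is then clamped (``r``
    capped at 1, ``n_streamlined`` floored at 0) so that
    ``n_full + n_streamlined == backbone_rel`` always holds.
    """
    if backbone_rel <= 0:
        raise ValueError("backbone relative coverage must be > 0")
    if amr_rel < 0:
        raise ValueError("AMR relative coverage must be >= 0")
    n_full = min(amr_rel, backbone_rel)
    n_streamlined = backbone_rel - n_full
    r = min(amr_rel / backbone_rel, 1.0)
    return MixtureEstimate(
        backbone_rel=backbone_rel,
        amr_rel=amr_rel,
        n_full=n_full,
        n_streamlined=n_streamlined,
        r=r,
        streamlined_fraction=1.0 - r,
    )


def copA_consistency(mixture: MixtureEstimate, copA_star_freq: float) -> float:
    """Residual between an observed backbone-allele frequency and the mixture.

    Under the two-molecule model every streamlined copy carries the mutant
    backbone allele (``copA*``) and every full-length copy the ancestral one,
    so the allele frequency should equal ``streamlined_fraction``.  Returns
    ``copA_star_freq - streamlined_fraction``; values near zero support the
    two-molecule interpretation.
    """
    if not 0.0 <= copA_star_freq <= 1.0:
        raise ValueError("allele frequency must be in [0, 1]")
    return copA_star_freq - mixture.streamlined_fraction


def _rolling_median(x: np.ndarray, window: int) -> np.ndarray:
    return (
        pd.Series(x)
        .rolling(window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )


def _runs_below(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, end) 0-based inclusive runs of True."""
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1) - 1
    return list(zip(starts, ends))


def detect_deletions(
    profile: CoverageProfile,
    window: int = 501,
    min_length: int = 5000,
) -> list[DeletionCall]:
    """All qualifying low-coverage runs, longest first.

    The depth is median-smoothed (window in bases), split into two robust
    levels by iterated 1-D two-medians, and thresholded at the level
    midpoint.  Runs of at least ``min_length`` below-threshold bases qualify,
    provided the level separation exceeds twice the noise scale of the
    smoothed depth (normalised MAD outside the candidate runs) — a guard that
    rejects flat noisy profiles.  Calls are invariant to global depth scaling.
    """
    if profile.length <= window:
        raise ValueError("profile must be longer than the smoothing window")
    raw = profile.depth
    if np.all(raw == 0):
        raise ValueError("degenerate profile: all depths are zero")
    smooth = _rolling_median(raw, window)

    # Robust two-level split (1-D k-medians, k=2).
    lo_level, hi_level = float(smooth.min()), float(smooth.max())
    threshold = 0.5 * (lo_level + hi_level)
    for _ in range(50):
        below = smooth < threshold
        if not below.any() or below.all():
            break
        lo_level = float(np.median(smooth[below]))
        hi_level = float(np.median(smooth[~below]))
        new_threshold = 0.5 * (lo_level + hi_level)
        if new_threshold == threshold:
            break
        threshold = new_threshold

    below = smooth < threshold
    runs = [r for r in _runs_below(below) if r[1] - r[0] + 1 >= min_length]
    if not runs:
        return []

    candidate = np.zeros(profile.length, dtype=bool)
    for s, e in runs:
        candidate[s : e + 1] = True
    outside = smooth[~candidate]
    noise = 1.4826 * float(np.median(np.abs(outside - np.median(outside))))
    if hi_level - lo_level <= 2.0 * noise:
        return []

    calls = [
        DeletionCall(
            start=int(s) + 1,
            end=int(e) + 1,
            inside_level=float(np.median(smooth[s : e + 1])),
            outside_level=hi_level,
            threshold=threshold,
        )
        for s, e in runs
    ]
    calls.sort(key=lambda c: c.length, reverse=True)
    return calls


def detect_deletion(
    profile: CoverageProfile,
    window: int = 501,
    min_length: int = 5000,
) -> DeletionCall | None:
    """Longest qualifying deletion call, or None (see :func:`detect_deletions`)."""
    calls = detect_deletions(profile, window=window, min_length=min_length)
    return calls[0] if calls else None


def clone_report(
    profile: CoverageProfile,
    regions: RegionSet | None = None,
    copA_star_freq: float | None = None,
    window: int = 501,
    min_length: int = 5000,
) -> dict:
    """Per-clone summary: region means, relative coverages, mixture estimate
    and deletion call, as a JSON-serialisable dict (one row per clone when
    concatenated)."""
    regions = regions or DEFAULT_REGIONS
    if profile.chrom_mean is None:
        raise ValueError("clone_report requires a chromosome mean depth")
    backbone = region_mean(profile, regions, "backbone")
    amr = region_mean(profile, regions, "AMR")
    backbone_rel = relative_coverage(backbone, profile.chrom_mean)
    amr_rel = relative_coverage(amr, profile.chrom_mean)
    mixture = estimate_mixture(backbone_rel, amr_rel)
    call = detect_deletion(profile, window=window, min_length=min_length)
    report = {
        "clone": profile.name,
        "backbone_mean_depth": backbone,
        "amr_mean_depth": amr,
        "chrom_mean_depth": profile.chrom_mean,
        "backbone_rel": backbone_rel,
        "amr_rel": amr_rel,
        "n_full": mixture.n_full,
        "n_streamlined": mixture.n_streamlined,
        "amr_relative_frequency": mixture.r,
        "streamlined_fraction": mixture.streamlined_fraction,
        "deletion_start": call.start if call else None,
        "deletion_end": call.end if call else None,
        "deletion_length": call.length if call else None,
    }
    if copA_star_freq is not None:
        report["copA_star_freq"] = copA_star_freq
        report["copA_residual"] = copA_consistency(mixture, copA_star_freq)
    return report
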