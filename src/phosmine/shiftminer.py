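"""Mine candidate phosphopeptide signals from paired peak lists.

A phosphopeptide carrying n phosphate groups loses n x 79.966 Da (HPO3)
upon alkaline-phosphatase treatment.  Comparing the neutral masses of
features in an untreated run against those in the matched AP-treated run
therefore reveals phosphopeptides as peak pairs whose mass difference is
a multiple of the phosphate-group mass, eluting at nearly the same
retention time.

Matching is performed on neutral monoisotopic mass rather than raw m/z,
so the two partners of a pair may be detected at different charge states;
``MinerParams.require_same_charge`` restores strict same-charge matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .peaklists import PHOSPHO_MASS, Peak, PeakList

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MinerParams:
    """Parameters of the mass-shift search.

    Defaults follow a cell-lysate pTyr study on an Orbitrap instrument:
    79.966 Da shift, 0.05 Da mass tolerance, 5 min retention-time
    tolerance, up to 5 phosphate groups, charge state at least 2, and a
    top-3000 intensity cut-off.  ``top_n`` may be the string ``"auto"``
    to pick the cut at the intensity-curve knee (largest slope change).
    ``delta_mass`` is user-settable so other mass-shifting treatments can
    be mined with the same machinery.
    """

    delta_mass: float = PHOSPHO_MASS
    mass_tol: float = 0.05
    rt_tol: float = 5.0
    max_mods: int = 5
    min_charge: int = 2
    top_n: Union[int, str, None] = 3000
    intensity_floor: float = 0.0
    require_same_charge: bool = False

    def __post_init__(self) -> None:
        if self.delta_mass <= 0:
            raise ValueError("delta_mass must be positive")
        if self.mass_tol <= 0:
            raise ValueError("mass_tol must be positive")
        if self.rt_tol < 0:
            raise ValueError("rt_tol must be non-negative")
        if self.max_mods < 1:
            raise ValueError("max_mods must be >= 1")
        if self.min_charge < 1:
            raise ValueError("min_charge must be >= 1")
        if isinstance(self.top_n, str) and self.top_n != "auto":
            raise ValueError("top_n must be an integer, 'auto', or None")


@dataclass(frozen=True)
class ShiftCandidate:
    """A matched untreated/treated peak pair with inferred phosphate count.

    ``mass_error`` is signed: observed shift minus n_mods * delta_mass.
    """

    untreated_peak: Peak
    treated_peak: Peak
    n_mods: int
    mass_error: float
    rt_diff: float
    replicate: int

    def __post_init__(self) -> None:
        if self.n_mods < 1:
            raise ValueError("n_mods must be >= 1")
        mu = self.untreated_peak.neutral_mass
        mt = self.treated_peak.neutral_mass
        if mu is not None and mt is not None and mu <= mt:
            raise ValueError(
                "untreated mass must exceed treated mass "
                f"({mu:.4f} <= {mt:.4f})"
            )


@dataclass
class CandidateSet:
    """Replicate-merged candidates for one experimental condition."""

    condition: str
    candidates: list[ShiftCandidate] = field(default_factory=list)
    support: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.candidates)


def intensity_chart_data(peaks: PeakList | Sequence[Peak]) -> list[tuple[int, float]]:
    """Descending intensity-vs-rank series for cut-off inspection charts."""
    intensities = sorted((p.intensity for p in peaks), reverse=True)
    return [(rank, inten) for rank, inten in enumerate(intensities, start=1)]


def intensity_knee(peaks: PeakList | Sequence[Peak]) -> int:
    """Suggest a top-N cut at the greatest slope change of the intensity curve.

    Intensities are sorted descending; the suggested N is the 1-based
    rank immediately before the largest drop between consecutive sorted
    intensities, ties broken toward the smaller N.  With fewer than three
    peaks there is no interior knee and the total count is returned.
    """
    intensities = sorted((p.intensity for p in peaks), reverse=True)
    n = len(intensities)
    if n < 3:
        logger.warning("intensity_knee: fewer than 3 peaks, returning %d", n)
        return n
    drops = np.diff(intensities)  # non-positive values
    best = int(np.argmin(drops))  # first occurrence wins -> smaller N
    if drops[best] == 0:  # flat series: no knee, retain everything
        return n
    return best + 1


def filter_peaks(peaks: PeakList, params: MinerParams) -> PeakList:
    """Apply charge, intensity-floor and top-N filters to a peak list.

    Peaks lacking a charge are dropped whenever ``min_charge > 1``.  The
    surviving peaks are ranked by descending intensity (ties broken by
    ascending m/z for determinism) and truncated to ``top_n``.
    """
    kept = [
        p
        for p in peaks
        if p.intensity >= params.intensity_floor
        and (
            (p.charge is not None and p.charge >= params.min_charge)
            or (p.charge is None and params.min_charge <= 1)
        )
    ]
    kept.sort(key=lambda p: (-p.intensity, p.mz))
    top_n = params.top_n
    if top_n == "auto":
        top_n = intensity_knee(kept)
    if top_n is not None:
        kept = kept[: int(top_n)]
    return peaks.with_peaks(kept)


def mine_pair(
    untreated: PeakList,
    treated: PeakList,
    params: MinerParams = MinerParams(),
) -> list[ShiftCandidate]:
    """Find all untreated/treated peak pairs consistent with phosphate loss.

    For every untreated peak u and every phosphate count n in
    1..max_mods, a treated peak t is a match when
    ``|(mass_u - mass_t) - n * delta_mass| <= mass_tol`` and
    ``|rt_u - rt_t| <= rt_tol``.  When several t match the same (u, n),
    only the one with the smallest |mass_error| (then smallest |rt_diff|)
    is kept; a u may still yield candidates at several distinct n.

    Implemented as a sort-by-mass binary-window scan; the output is
    identical to exhaustive enumeration of every (u, t, n) triple.
    """
    if untreated.replicate != treated.replicate:
        logger.warning(
            "pairing replicate %d against %d",
            untreated.replicate,
            treated.replicate,
        )
    t_peaks = [p for p in treated if p.neutral_mass is not None]
    if not t_peaks:
        return []
    t_peaks.sort(key=lambda p: p.neutral_mass)
    t_masses = np.array([p.neutral_mass for p in t_peaks])

    out: list[ShiftCandidate] = []
    for u in untreated:
        mu = u.neutral_mass
        if mu is None:
            continue
        for n in range(1, params.max_mods + 1):
            target = mu - n * params.delta_mass
            lo = int(np.searchsorted(t_masses, target - params.mass_tol, "left"))
            hi = int(np.searchsorted(t_masses, target + params.mass_tol, "right"))
            best: Optional[tuple[float, float, Peak]] = None
            for t in t_peaks[lo:hi]:
                rt_diff = u.rt - t.rt
                if abs(rt_diff) > params.rt_tol:
                    continue
                if params.require_same_charge and u.charge != t.charge:
                    continue
                mass_error = (mu - t.neutral_mass) - n * params.delta_mass
                key = (abs(mass_error), abs(rt_diff))
                if best is None or key < (abs(best[0]), abs(best[1])):
                    best = (mass_error, rt_diff, t)
            if best is not None:
                out.append(
                    ShiftCandidate(
                        untreated_peak=u,
                        treated_peak=best[2],
                        n_mods=n,
                        mass_error=best[0],
                        rt_diff=best[1],
                        replicate=untreated.replicate,
                    )
                )
    return out


def merge_replicates(
    per_replicate: Sequence[Iterable[ShiftCandidate]],
    cluster_mz_tol: float = 0.02,
    cluster_rt_tol: float = 2.0,
    min_support: int = 1,
    condition: str = "untreated",
) -> CandidateSet:
    """Merge candidates observed across replicate pairs into one set.

    Candidates are clustered greedily on their untreated-peak (m/z, rt):
    seeds are taken in descending untreated intensity; each candidate
    joins the first seed within both tolerances, else starts a new
    cluster.  The cluster representative is the member of highest
    untreated intensity, and ``support`` counts the distinct replicates
    contributing to the cluster.  Clusters with support below
    ``min_support`` are discarded.
    """
    n_reps = len(per_replicate)
    if min_support > n_reps:
        logger.warning(
            "min_support %d exceeds replicate count %d: empty result",
            min_support,
            n_reps,
        )
        return CandidateSet(condition=condition)

    flat: list[ShiftCandidate] = [c for rep in per_replicate for c in rep]
    flat.sort(
        key=lambda c: (-c.untreated_peak.intensity, c.untreated_peak.mz, c.n_mods)
    )
    seeds: list[ShiftCandidate] = []
    members: list[list[ShiftCandidate]] = []
    for cand in flat:
        placed = False
        for i, seed in enumerate(seeds):
            if (
                abs(cand.untreated_peak.mz - seed.untreated_peak.mz)
                <= cluster_mz_tol
                and abs(cand.untreated_peak.rt - seed.untreated_peak.rt)
                <= cluster_rt_tol
            ):
                members[i].append(cand)
                placed = True
                break
        if not placed:
            seeds.append(cand)
            members.append([cand])

    out = CandidateSet(condition=condition)
    for cluster in members:
        support = len({c.replicate for c in cluster})
        if support < min_support:
            continue
        rep = max(cluster, key=lambda c: c.untreated_peak.intensity)
        out.candidates.append(rep)
        out.support.append(support)
    return out


# ---------------------------------------------------------------------------
# Tabular serialisation of candidates

_CANDIDATE_COLUMNS = [
    "untreated_mz",
    "untreated_charge",
    "untreated_mass",
    "untreated_rt",
    "untreated_intensity",
    "treated_mz",
    "treated_mass",
    "treated_rt",
    "n_mods",
    "mass_error",
    "rt_diff",
    "replicate",
    "support",
]


def candidates_to_frame(
    candidates: Iterable[ShiftCandidate],
    support: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Flatten candidates into the standard output table."""
    rows = []
    candidates = list(candidates)
    for i, c in enumerate(candidates):
        rows.append(
            {
                "untreated_mz": c.untreated_peak.mz,
                "untreated_charge": c.untreated_peak.charge,
                "untreated_mass": c.untreated_peak.neutral_mass,
                "untreated_rt": c.untreated_peak.rt,
                "untreated_intensity": c.untreated_peak.intensity,
                "treated_mz": c.treated_peak.mz,
                "treated_mass": c.treated_peak.neutral_mass,
                "treated_rt": c.treated_peak.rt,
                "n_mods": c.n_mods,
                "mass_error": c.mass_error,
                "rt_diff": c.rt_diff,
                "replicate": c.replicate,
                "support": support[i] if support is not None else 1,
            }
        )
    return pd.DataFrame(rows, columns=_CANDIDATE_COLUMNS)


def write_candidates(
    candidates: Iterable[ShiftCandidate] | CandidateSet, path
) -> None:
    if isinstance(candidates, CandidateSet):
        frame = candidates_to_frame(candidates.candidates, candidates.support)
    else:
        frame = candidates_to_frame(candidates)
    frame.to_csv(path, sep="\t", index=False)


def read_candidate_table(path) -> pd.DataFrame:
    """Read a candidate table written by :func:`write_candidates`."""
    frame = pd.read_csv(path, sep="\t")
    missing = set(["untreated_mz", "untreated_rt", "n_mods"]) - set(frame.columns)
    if missing:
        raise ValueError(f"candidate table missing columns {sorted(missing)}")
    return frame
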