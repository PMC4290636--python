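"""Build deduplicated, time-segmented m/z inclusion lists for targeted MS/MS.

Mined candidates from one or more conditions and replicates are collapsed
on rounded untreated m/z (instruments treat, e.g., 812.8579 and 812.8612
as the same 812.86 target), assigned to equal retention-time segments of
the elution range, and given per-target retention-time windows.

Two window modes exist because instruments accept either fixed segment
windows or per-target windows: ``segment`` pads the segment bounds by the
extra tolerance, ``candidate_extent`` (default) pads the observed RT
extent of the merged target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, ROUND_HALF_UP, Decimal
from statistics import median
from typing import Iterable, Optional, Sequence

import pandas as pd

from .shiftminer import CandidateSet, ShiftCandidate

logger = logging.getLogger(__name__)


def round_mz(mz: float, decimals: int, mode: str = "half_up") -> float:
    """Round an m/z value to ``decimals`` places, half away from zero.

    Decimal arithmetic avoids binary-float artefacts (1.005 -> 1.01).
    ``mode`` may be ``"half_even"`` for banker's rounding.
    """
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    rounding = ROUND_HALF_UP if mode == "half_up" else ROUND_HALF_EVEN
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(mz)).quantize(quantum, rounding=rounding))


@dataclass(frozen=True)
class InclusionParams:
    """Elution range, segmentation and window parameters.

    A typical nano-LC setup: range 10-60 min, 10 segments (5 min each),
    1.5 min extra tolerance, m/z rounded to 2 decimals.
    """

    t_start: float = 10.0
    t_end: float = 60.0
    n_segments: int = 10
    extra_rt_tol: float = 1.5
    round_decimals: int = 2
    window_mode: str = "candidate_extent"
    max_per_segment: Optional[int] = None
    rounding_mode: str = "half_up"

    def __post_init__(self) -> None:
        if self.t_start >= self.t_end:
            raise ValueError("t_start must be < t_end")
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if self.extra_rt_tol < 0:
            raise ValueError("extra_rt_tol must be >= 0")
        if self.round_decimals < 0:
            raise ValueError("round_decimals must be >= 0")
        if self.window_mode not in ("segment", "candidate_extent"):
            raise ValueError("window_mode must be 'segment' or 'candidate_extent'")

    @property
    def segment_width(self) -> float:
        return (self.t_end - self.t_start) / self.n_segments


@dataclass
class Precursor:
    """A deduplicated m/z target: candidates sharing one rounded m/z."""

    mz_rounded: float
    member_rts: list[float]
    member_mzs: list[float]
    conditions: set[str]
    n_mods_values: list[int]
    charges: set[int] = field(default_factory=set)

    @property
    def representative_rt(self) -> float:
        """Median member RT — robust to an outlier replicate."""
        return float(median(self.member_rts))

    @property
    def n_mods(self) -> int:
        return min(self.n_mods_values)


@dataclass(frozen=True)
class InclusionEntry:
    """One inclusion-list row: an m/z target with its RT window."""

    mz_rounded: float
    window_start: float
    window_end: float
    segment_index: int
    source_conditions: frozenset[str]
    n_mods: int
    charges: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.window_start >= self.window_end:
            raise ValueError("window_start must be < window_end")
        if self.mz_rounded <= 0:
            raise ValueError("mz_rounded must be positive")


def combine_conditions(sets: Sequence[CandidateSet]) -> CandidateSet:
    """Union candidate sets from different experimental conditions.

    Each candidate keeps its origin label (carried via the per-set
    condition); collisions between conditions are merged later by
    :func:`deduplicate`.
    """
    combined = CandidateSet(condition="+".join(s.condition for s in sets) or "none")
    for s in sets:
        combined.candidates.extend(s.candidates)
        support = s.support if s.support else [1] * len(s.candidates)
        combined.support.extend(support)
        combined_labels = getattr(combined, "_labels", None)
        if combined_labels is None:
            combined._labels = []  # type: ignore[attr-defined]
        combined._labels.extend([s.condition] * len(s.candidates))  # type: ignore[attr-defined]
    return combined


def _candidate_condition_labels(cset: CandidateSet) -> list[str]:
    labels = getattr(cset, "_labels", None)
    if labels is None:
        return [cset.condition] * len(cset.candidates)
    return labels


def deduplicate(
    candidate_sets: CandidateSet | Sequence[CandidateSet],
    decimals: int = 2,
    rounding_mode: str = "half_up",
) -> list[Precursor]:
    """Collapse candidates whose rounded untreated m/z collide.

    Duplicated m/z values arising from different biological replicas or
    conditions become a single precursor whose RT extent is the union of
    member RTs and whose condition set is the union of member origins.
    Idempotent: deduplicating the output again changes nothing.
    """
    if isinstance(candidate_sets, CandidateSet):
        candidate_sets = [candidate_sets]
    groups: dict[float, Precursor] = {}
    for cset in candidate_sets:
        labels = _candidate_condition_labels(cset)
        for cand, label in zip(cset.candidates, labels):
            key = round_mz(cand.untreated_peak.mz, decimals, rounding_mode)
            pre = groups.get(key)
            if pre is None:
                pre = Precursor(
                    mz_rounded=key,
                    member_rts=[],
                    member_mzs=[],
                    conditions=set(),
                    n_mods_values=[],
                )
                groups[key] = pre
            pre.member_rts.append(cand.untreated_peak.rt)
            pre.member_mzs.append(cand.untreated_peak.mz)
            pre.conditions.add(label)
            pre.n_mods_values.append(cand.n_mods)
            if cand.untreated_peak.charge is not None:
                pre.charges.add(cand.untreated_peak.charge)
    return [groups[k] for k in sorted(groups)]


def build_inclusion_list(
    precursors: Sequence[Precursor],
    params: InclusionParams = InclusionParams(),
) -> list[InclusionEntry]:
    """Assign precursors to equal RT segments and attach windows.

    The range [t_start, t_end] is split into ``n_segments`` half-open
    equal segments [s_i, s_{i+1}) (last segment closed).  Each precursor
    lands in the segment containing its representative RT (median of
    member RTs); out-of-range precursors are clamped to the nearest
    segment and logged.  Windows are the segment bounds or the member RT
    extent, padded by ``extra_rt_tol`` on both sides.
    """
    width = params.segment_width
    entries: list[InclusionEntry] = []
    per_segment: dict[int, int] = {}
    for pre in precursors:
        rt = pre.representative_rt
        idx = int((rt - params.t_start) // width)
        if rt < params.t_start or rt >= params.t_end:
            clamped = min(max(idx, 0), params.n_segments - 1)
            if rt != params.t_end or idx != params.n_segments:
                logger.info(
                    "precursor m/z %.4f RT %.2f outside [%g, %g]: "
                    "clamped to segment %d",
                    pre.mz_rounded,
                    rt,
                    params.t_start,
                    params.t_end,
                    clamped,
                )
            idx = clamped
        idx = min(max(idx, 0), params.n_segments - 1)
        if (
            params.max_per_segment is not None
            and per_segment.get(idx, 0) >= params.max_per_segment
        ):
            logger.info(
                "segment %d full (%d targets): dropping m/z %.4f",
                idx,
                params.max_per_segment,
                pre.mz_rounded,
            )
            continue
        if params.window_mode == "segment":
            start = params.t_start + idx * width - params.extra_rt_tol
            end = params.t_start + (idx + 1) * width + params.extra_rt_tol
        else:
            start = min(pre.member_rts) - params.extra_rt_tol
            end = max(pre.member_rts) + params.extra_rt_tol
            if start == end:  # degenerate single-point extent
                start -= 1e-6
                end += 1e-6
        entries.append(
            InclusionEntry(
                mz_rounded=pre.mz_rounded,
                window_start=start,
                window_end=end,
                segment_index=idx,
                source_conditions=frozenset(pre.conditions),
                n_mods=pre.n_mods,
                charges=frozenset(pre.charges),
            )
        )
        per_segment[idx] = per_segment.get(idx, 0) + 1
    entries.sort(key=lambda e: (e.segment_index, e.mz_rounded))
    return entries


# ---------------------------------------------------------------------------
# Output formats

def inclusion_to_frame(entries: Iterable[InclusionEntry]) -> pd.DataFrame:
    """Instrument-style inclusion table."""
    rows = [
        {
            "Mass [m/z]": e.mz_rounded,
            "Formula": "",
            "Species": "",
            "CS [z]": ";".join(str(z) for z in sorted(e.charges)),
            "Polarity": "Positive",
            "Start [min]": round(e.window_start, 2),
            "End [min]": round(e.window_end, 2),
            "Segment": e.segment_index,
        }
        for e in entries
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "Mass [m/z]",
            "Formula",
            "Species",
            "CS [z]",
            "Polarity",
            "Start [min]",
            "End [min]",
            "Segment",
        ],
    )


def write_inclusion_csv(
    entries: Sequence[InclusionEntry],
    path,
    plain: bool = False,
    split_segments: bool = False,
) -> list[str]:
    """Write the inclusion list; optionally one file per segment.

    ``plain`` writes the 3-column (mz, start, end) variant.  Returns the
    list of paths written.
    """
    from pathlib import Path

    path = Path(path)
    written: list[str] = []

    def _write(sub: Sequence[InclusionEntry], p) -> None:
        if plain:
            frame = pd.DataFrame(
                {
                    "mz": [e.mz_rounded for e in sub],
                    "start": [round(e.window_start, 2) for e in sub],
                    "end": [round(e.window_end, 2) for e in sub],
                }
            )
        else:
            frame = inclusion_to_frame(sub)
        frame.to_csv(p, index=False)
        written.append(str(p))

    if split_segments:
        for idx in sorted({e.segment_index for e in entries}):
            sub = [e for e in entries if e.segment_index == idx]
            _write(sub, path.with_name(f"{path.stem}_segment{idx}{path.suffix}"))
    else:
        _write(entries, path)
    return written
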