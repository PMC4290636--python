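"""Link phosphopeptide identifications to label-free quantification features.

Search-engine peptide-spectrum matches (Mascot-style CSV exports) from the
targeted MS/MS runs are joined to MS1 quantification features
(Progenesis/mzMine-style CSV) on m/z, retention time and charge, filtered
by ion score and phosphorylation type, and summarised as a differential
table with control/treatment abundance ratios and one-way ANOVA p-values.

Also provides the localization delta score: the difference between the
top two search-engine ion scores among alternative phosphosite
placements of the same peptide sequence (larger = more confident site
assignment).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

PHOSPHO_RESIDUES = frozenset("STY")

#: Long-form labels accepted for the phospho-type filter.
_PHOSPHO_ALIASES = {
    "pSer": "S", "pThr": "T", "pTyr": "Y",
    "S": "S", "T": "T", "Y": "Y",
}


class LinkerConfigError(ValueError):
    """Raised for inconsistent linker configuration (e.g. run/group maps)."""


def normalize_phospho_filter(values: Iterable[str]) -> frozenset[str]:
    out = set()
    for v in values:
        if v not in _PHOSPHO_ALIASES:
            raise LinkerConfigError(
                f"unknown phospho type {v!r}; expected pSer/pThr/pTyr or S/T/Y"
            )
        out.add(_PHOSPHO_ALIASES[v])
    return frozenset(out)


# ---------------------------------------------------------------------------
# Modification-string parsing

_SITE_TOKEN = re.compile(r"\bp([STY])(\d+)\b")


def parse_mod_string(
    sequence: str, mod_string: str, dialect: str = "mascot_csv"
) -> frozenset[tuple[str, int]]:
    """Extract phosphosite assignments from a modification annotation.

    In the ``mascot_csv`` dialect, phosphosites appear as tokens
    ``pS<pos>`` / ``pT<pos>`` / ``pY<pos>`` with 1-based positions, e.g.
    ``"Phospho (Y): pY10"`` or ``"2 Phospho (ST): pT2, pS5"``.  Any other
    modifications (oxidation, deamidation, carbamidomethyl, ...) are
    ignored.  A position that falls outside the sequence or names a
    residue the sequence does not carry there is an inconsistency.

    Returns the set of (residue letter, position) sites.
    """
    if dialect != "mascot_csv":
        raise LinkerConfigError(f"unknown mod-string dialect {dialect!r}")
    sites: set[tuple[str, int]] = set()
    for residue, pos_str in _SITE_TOKEN.findall(mod_string or ""):
        pos = int(pos_str)
        if not 1 <= pos <= len(sequence):
            raise ValueError(
                f"phosphosite position {pos} outside sequence of "
                f"length {len(sequence)}"
            )
        if sequence[pos - 1] != residue:
            raise ValueError(
                f"phosphosite {residue}{pos} disagrees with sequence "
                f"residue {sequence[pos - 1]!r}"
            )
        sites.add((residue, pos))
    return frozenset(sites)


@dataclass(frozen=True)
class PeptideID:
    """One peptide-spectrum match from a database search engine."""

    sequence: str
    mod_string: str
    mz: float
    charge: int
    rt: float
    score: float
    accession: str = ""
    phospho_sites: frozenset[tuple[str, int]] = frozenset()

    def __post_init__(self) -> None:
        for residue, pos in self.phospho_sites:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"site position {pos} outside sequence")
            if self.sequence[pos - 1] != residue:
                raise ValueError(
                    f"site {residue}{pos} disagrees with sequence residue "
                    f"{self.sequence[pos - 1]!r}"
                )

    @property
    def site_residues(self) -> frozenset[str]:
        return frozenset(r for r, _ in self.phospho_sites)

    @property
    def marked_sequence(self) -> str:
        """Sequence with phosphosites marked, e.g. DEHLSTLDApYRPK."""
        positions = {pos for _, pos in self.phospho_sites}
        return "".join(
            ("p" + aa) if i + 1 in positions else aa
            for i, aa in enumerate(self.sequence)
        )


def make_peptide_id(
    sequence: str,
    mod_string: str,
    mz: float,
    charge: int,
    rt: float,
    score: float,
    accession: str = "",
    dialect: str = "mascot_csv",
) -> PeptideID:
    """Build a :class:`PeptideID`, parsing the modification string."""
    sites = parse_mod_string(sequence, mod_string, dialect)
    return PeptideID(
        sequence=sequence,
        mod_string=mod_string,
        mz=mz,
        charge=charge,
        rt=rt,
        score=score,
        accession=accession,
        phospho_sites=sites,
    )


@dataclass
class QuantFeature:
    """One label-free quantified MS1 feature.

    ``abundances`` maps condition label -> run label -> non-negative
    abundance; every condition must contribute at least one run.
    """

    feature_id: str
    mz: float
    charge: int
    rt: float
    abundances: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        if not self.abundances:
            raise LinkerConfigError(
                f"feature {self.feature_id}: no abundance groups"
            )
        for cond, runs in self.abundances.items():
            if not runs:
                raise LinkerConfigError(
                    f"feature {self.feature_id}: condition {cond!r} has no runs"
                )
            for run, value in runs.items():
                if value < 0:
                    raise ValueError(
                        f"feature {self.feature_id}: negative abundance in "
                        f"{cond}/{run}"
                    )

    def group_values(self, condition: str) -> list[float]:
        return list(self.abundances[condition].values())


@dataclass(frozen=True)
class LinkParams:
    """Matching tolerances and identification filters.

    Defaults follow a pTyr study: ion score above 25, 0.2 Da m/z
    tolerance, 2 min retention-time tolerance; ``phospho_filter`` keeps
    only peptides carrying at least one phosphosite of the listed
    residue types (default: any of S/T/Y).
    """

    mz_tol: float = 0.2
    rt_tol: float = 2.0
    min_score: float = 25.0
    phospho_filter: frozenset[str] = PHOSPHO_RESIDUES
    require_charge_match: bool = True
    keep_all_matches: bool = False

    def __post_init__(self) -> None:
        if self.mz_tol <= 0 or self.rt_tol <= 0:
            raise ValueError("tolerances must be positive")
        object.__setattr__(
            self, "phospho_filter", normalize_phospho_filter(self.phospho_filter)
        )


@dataclass
class LinkedRecord:
    """A peptide identification joined to its quantification feature."""

    id: PeptideID
    feature: QuantFeature
    mz_diff: float
    rt_diff: float
    group_ratio: float
    p_value: Optional[float]


@dataclass
class LinkResult:
    linked: list[LinkedRecord] = field(default_factory=list)
    unlinked: list[PeptideID] = field(default_factory=list)
    filtered_out: int = 0


def group_ratio(
    feature: QuantFeature, control: str, treatment: str
) -> float:
    """Mean control abundance over mean treatment abundance.

    A zero treatment mean with non-zero control signal yields the
    ``inf`` sentinel (reported as "infinity" in tables); 0/0 is NaN.
    """
    num = float(np.mean(feature.group_values(control)))
    den = float(np.mean(feature.group_values(treatment)))
    if den == 0:
        return math.inf if num > 0 else math.nan
    return num / den


def anova_p_value(feature: QuantFeature) -> Optional[float]:
    """One-way ANOVA p across condition groups; None if any group has < 2 runs."""
    groups = [feature.group_values(c) for c in feature.abundances]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        return None
    if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        return 1.0  # all values identical: no evidence of any effect
    stat, p = stats.f_oneway(*groups)
    return float(p) if np.isfinite(p) else None


def link(
    ids: Sequence[PeptideID],
    features: Sequence[QuantFeature],
    params: LinkParams = LinkParams(),
    control: str = "control",
    treatment: str = "treatment",
) -> LinkResult:
    """Join identifications to quantification features.

    Identifications scoring below ``min_score`` or carrying no
    phosphosite of a residue type in ``phospho_filter`` are dropped.
    Each surviving identification links to the feature minimizing
    |mz_diff| (then |rt_diff|) among features within both tolerances and
    (when required) of equal charge; identifications with no qualifying
    feature are reported unlinked.  ``keep_all_matches`` emits every
    qualifying feature instead of the single best.

    The exhaustive all-pairs scan is the definition; the feature table is
    pre-sorted on m/z only to bound the scan window.
    """
    for f in features:
        groups = set(f.abundances)
        if not {control, treatment} <= groups:
            raise LinkerConfigError(
                f"feature {f.feature_id}: abundance groups {sorted(groups)} "
                f"do not cover conditions {control!r} and {treatment!r}"
            )

    feats = sorted(features, key=lambda f: f.mz)
    fmz = np.array([f.mz for f in feats])
    result = LinkResult()
    for pid in ids:
        if pid.score < params.min_score or not (
            pid.site_residues & params.phospho_filter
        ):
            result.filtered_out += 1
            continue
        lo = int(np.searchsorted(fmz, pid.mz - params.mz_tol, "left"))
        hi = int(np.searchsorted(fmz, pid.mz + params.mz_tol, "right"))
        matches: list[tuple[float, float, QuantFeature]] = []
        for f in feats[lo:hi]:
            mz_diff = pid.mz - f.mz
            rt_diff = pid.rt - f.rt
            if abs(mz_diff) > params.mz_tol or abs(rt_diff) > params.rt_tol:
                continue
            if params.require_charge_match and pid.charge != f.charge:
                continue
            matches.append((mz_diff, rt_diff, f))
        if not matches:
            result.unlinked.append(pid)
            continue
        matches.sort(key=lambda m: (abs(m[0]), abs(m[1]), m[2].feature_id))
        chosen = matches if params.keep_all_matches else matches[:1]
        for mz_diff, rt_diff, f in chosen:
            result.linked.append(
                LinkedRecord(
                    id=pid,
                    feature=f,
                    mz_diff=mz_diff,
                    rt_diff=rt_diff,
                    group_ratio=group_ratio(f, control, treatment),
                    p_value=anova_p_value(f),
                )
            )
    return result


def md_score(scores: Sequence[float]) -> float:
    """Localization delta score for one peptide's alternative site placements.

    Given the ion scores of every candidate phosphosite assignment of the
    same peptide sequence, returns top score minus second score.  With a
    single candidate placement there is no competitor and the top score
    itself is returned (documented convention).  Order-invariant and
    non-negative.
    """
    if len(scores) == 0:
        raise ValueError("md_score requires at least one candidate assignment")
    ranked = sorted(scores, reverse=True)
    if len(ranked) == 1:
        return float(ranked[0])
    return float(ranked[0] - ranked[1])


def md_scores_by_sequence(ids: Iterable[PeptideID]) -> dict[str, float]:
    """MD-score per peptide sequence over its alternative site placements."""
    by_seq: dict[str, list[float]] = {}
    for pid in ids:
        by_seq.setdefault(pid.sequence, []).append(pid.score)
    return {seq: md_score(scores) for seq, scores in by_seq.items()}


def summarize(linked: Sequence[LinkedRecord], alpha: float = 0.05) -> pd.DataFrame:
    """Differential table of linked records.

    Columns: accession, sequence (with phosphosite markup), m/z, ratio
    (control/treatment; inf rendered as "infinity"), ANOVA p-value,
    differential flag (p < alpha).  Sorted by ratio descending, records
    without a p-value retained but never flagged.
    """
    rows = []
    for rec in linked:
        rows.append(
            {
                "accession": rec.id.accession,
                "sequence": rec.id.marked_sequence,
                "mz": rec.id.mz,
                "ratio": rec.group_ratio,
                "p_value": rec.p_value,
                "differential": (
                    rec.p_value is not None and rec.p_value < alpha
                ),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["accession", "sequence", "mz", "ratio", "p_value", "differential"],
    )
    if len(frame):
        frame = frame.sort_values(
            "ratio", ascending=False, na_position="last", kind="mergesort"
        ).reset_index(drop=True)
    return frame


def format_ratio(value: float) -> str:
    if math.isinf(value):
        return "infinity"
    if math.isnan(value):
        return "NA"
    return f"{value:.2f}"


# ---------------------------------------------------------------------------
# CSV readers (Mascot-style id export, Progenesis-style quant export)

#: Default column names of the Mascot-style CSV this package consumes.
DEFAULT_ID_COLUMNS = {
    "sequence": "pep_seq",
    "mod_string": "pep_var_mod",
    "mz": "pep_exp_mz",
    "charge": "pep_exp_z",
    "rt": "pep_rt",
    "score": "pep_score",
    "accession": "prot_acc",
}


def read_ids_csv(
    path,
    columns: Mapping[str, str] = DEFAULT_ID_COLUMNS,
    dialect: str = "mascot_csv",
) -> list[PeptideID]:
    """Read a search-engine export; rows with inconsistent phosphosite
    annotations are excluded with a log entry."""
    frame = pd.read_csv(path)
    missing = [c for c in columns.values() if c not in frame.columns]
    if missing:
        raise LinkerConfigError(f"id table missing column(s) {missing}")
    out: list[PeptideID] = []
    for _, row in frame.iterrows():
        mod = row[columns["mod_string"]]
        mod = "" if pd.isna(mod) else str(mod)
        try:
            out.append(
                make_peptide_id(
                    sequence=str(row[columns["sequence"]]),
                    mod_string=mod,
                    mz=float(row[columns["mz"]]),
                    charge=int(row[columns["charge"]]),
                    rt=float(row[columns["rt"]]),
                    score=float(row[columns["score"]]),
                    accession=str(row[columns["accession"]]),
                    dialect=dialect,
                )
            )
        except ValueError as exc:
            logger.warning("excluding invalid id row: %s", exc)
    return out


def read_quant_csv(
    path,
    run_conditions: Mapping[str, str],
    mz_column: str = "mz",
    rt_column: str = "rt",
    charge_column: str = "charge",
    id_column: str = "feature_id",
) -> list[QuantFeature]:
    """Read a quantification export with one abundance column per run.

    ``run_conditions`` maps abundance column names to condition labels;
    every listed run column must exist in the file.
    """
    frame = pd.read_csv(path)
    missing = [c for c in (mz_column, rt_column, charge_column) if c not in frame.columns]
    missing += [r for r in run_conditions if r not in frame.columns]
    if missing:
        raise LinkerConfigError(f"quant table missing column(s) {missing}")
    if len(set(run_conditions.values())) < 2:
        raise LinkerConfigError(
            "run/condition map must cover at least two conditions"
        )
    out: list[QuantFeature] = []
    for i, row in frame.iterrows():
        abundances: dict[str, dict[str, float]] = {}
        for run, cond in run_conditions.items():
            abundances.setdefault(cond, {})[run] = float(row[run])
        fid = str(row[id_column]) if id_column in frame.columns else f"F{i}"
        out.append(
            QuantFeature(
                feature_id=fid,
                mz=float(row[mz_column]),
                charge=int(row[charge_column]),
                rt=float(row[rt_column]),
                abundances=abundances,
            )
        )
    return out


def write_linked_csv(
    linked: Sequence[LinkedRecord], path, alpha: float = 0.05
) -> None:
    frame = summarize(linked, alpha=alpha)
    frame["ratio"] = frame["ratio"].map(format_ratio)
    frame.to_csv(path, index=False)
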