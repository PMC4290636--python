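"""Canonical LC-MS peak model and delimited peak-list readers/writers.

Peak lists are the tab- or comma-delimited exports of upstream feature
detection software (msInspect-style: one header row, one monoisotopic
feature per row).  This module turns them into :class:`PeakList` objects
carrying neutral monoisotopic masses, which is the quantity the
dephosphorylation mass-shift miner compares.
"""

from __future__ import annotations

import glob as _glob
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Mass of a proton in Da, used to strip charging protons from m/z.
#: Fixed so that the neutral mass of (m/z 812.858, 2+) is 1623.701 Da.
PROTON_MASS = 1.00728

#: Monoisotopic mass of one phosphate group (HPO3) lost per
#: dephosphorylation event, in Da.
PHOSPHO_MASS = 79.966

#: Condition labels for the paired experiment.
UNTREATED = "untreated"
AP_TREATED = "ap_treated"
CONDITIONS = (UNTREATED, AP_TREATED)

MAX_REPLICATES = 6


class PeakListError(ValueError):
    """Raised for malformed peak-list configuration or content."""


def compute_neutral_mass(mz: float, charge: int) -> float:
    """Neutral monoisotopic mass from an observed m/z and charge state.

    M = z * (m/z) - z * m_proton

    Parameters
    ----------
    mz : float
        Observed mass-to-charge ratio in Thomson, must be positive.
    charge : int
        Positive charge state.

    Returns
    -------
    float
        Neutral monoisotopic mass in Da.

    Examples
    --------
    >>> round(compute_neutral_mass(812.858, 2), 3)
    1623.701
    """
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    if mz <= 0:
        raise ValueError(f"mz must be positive, got {mz}")
    return charge * mz - charge * PROTON_MASS


def mass_to_mz(mass: float, charge: int) -> float:
    """Inverse of :func:`compute_neutral_mass`."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (mass + charge * PROTON_MASS) / charge


@dataclass(frozen=True)
class Peak:
    """One monoisotopic LC-MS feature.

    ``mass`` is the neutral monoisotopic mass in Da; ``rt`` is in minutes.
    ``charge`` may be absent (None) for features the upstream software
    could not deconvolute; such peaks survive loading but are dropped by
    any filter requiring a minimum charge above 1.
    """

    run_id: str
    mz: float
    rt: float
    intensity: float
    charge: Optional[int] = None
    mass: Optional[float] = None
    scan: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise PeakListError(f"mz must be positive, got {self.mz}")
        if self.rt < 0:
            raise PeakListError(f"rt must be non-negative, got {self.rt}")
        if self.intensity < 0:
            raise PeakListError(
                f"intensity must be non-negative, got {self.intensity}"
            )
        if self.charge is not None and self.charge < 1:
            raise PeakListError(f"charge must be >= 1, got {self.charge}")
        if self.mass is not None and self.charge is not None:
            expected = compute_neutral_mass(self.mz, self.charge)
            if abs(self.mass - expected) > 0.01:
                raise PeakListError(
                    f"inconsistent mass {self.mass:.4f} vs {expected:.4f} "
                    f"computed from m/z {self.mz} at {self.charge}+"
                )

    @property
    def neutral_mass(self) -> Optional[float]:
        """Stored mass if present, else computed from (mz, charge)."""
        if self.mass is not None:
            return self.mass
        if self.charge is not None:
            return compute_neutral_mass(self.mz, self.charge)
        return None


@dataclass
class PeakList:
    """An ordered collection of peaks from one LC-MS run."""

    run_id: str
    condition: str
    replicate: int
    peaks: list[Peak] = field(default_factory=list)
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise PeakListError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if not 1 <= self.replicate <= MAX_REPLICATES:
            raise PeakListError(
                f"replicate must be in 1..{MAX_REPLICATES}, got {self.replicate}"
            )
        for p in self.peaks:
            if p.run_id != self.run_id:
                raise PeakListError(
                    f"peak run_id {p.run_id!r} != list run_id {self.run_id!r}"
                )

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def with_peaks(self, peaks: Iterable[Peak]) -> "PeakList":
        return PeakList(
            run_id=self.run_id,
            condition=self.condition,
            replicate=self.replicate,
            peaks=list(peaks),
            n_skipped=self.n_skipped,
        )


@dataclass(frozen=True)
class ColumnMapping:
    """Maps canonical field names to source column headers.

    ``columns`` keys are drawn from {mz, mass, rt, intensity, charge, scan};
    at least one of mz/mass plus rt and intensity must be mapped.
    ``rt_units`` converts seconds (msInspect's unit) to the canonical
    minutes on load.
    """

    columns: Mapping[str, str]
    rt_units: str = "minutes"
    delimiter: str = "\t"

    _CANONICAL = ("mz", "mass", "rt", "intensity", "charge", "scan")

    def __post_init__(self) -> None:
        unknown = set(self.columns) - set(self._CANONICAL)
        if unknown:
            raise PeakListError(f"unknown canonical fields: {sorted(unknown)}")
        if "mz" not in self.columns and "mass" not in self.columns:
            raise PeakListError("mapping must include 'mz' or 'mass'")
        for required in ("rt", "intensity"):
            if required not in self.columns:
                raise PeakListError(f"mapping must include {required!r}")
        if self.rt_units not in ("minutes", "seconds"):
            raise PeakListError(
                f"rt_units must be 'minutes' or 'seconds', got {self.rt_units!r}"
            )


#: Default mapping for msInspect peptide-feature TSV exports
#: (columns: scan, time, mz, mass, intensity, charge; time in seconds).
MSINSPECT_MAPPING = ColumnMapping(
    columns={
        "scan": "scan",
        "rt": "time",
        "mz": "mz",
        "mass": "mass",
        "intensity": "intensity",
        "charge": "charge",
    },
    rt_units="seconds",
    delimiter="\t",
)

#: Mapping matching this package's own simple TSV output
#: (mz, charge, rt, intensity), rt in minutes.
SIMPLE_MAPPING = ColumnMapping(
    columns={"mz": "mz", "charge": "charge", "rt": "rt", "intensity": "intensity"},
    rt_units="minutes",
    delimiter="\t",
)


def _coerce_float(value) -> Optional[float]:
    try:
        out = float(value)
    except (TypeError, ValueError):
        return None
    return out if out == out else None  # reject NaN


def _coerce_int(value) -> Optional[int]:
    f = _coerce_float(value)
    if f is None or f != int(f):
        return None
    return int(f)


def read_peaklist(
    path,
    mapping: ColumnMapping = SIMPLE_MAPPING,
    condition: str = UNTREATED,
    replicate: int = 1,
    run_id: Optional[str] = None,
) -> PeakList:
    """Read one delimited peak-list file into a :class:`PeakList`.

    Rows whose mandatory fields (m/z or mass, rt, intensity) cannot be
    parsed are skipped and counted in ``PeakList.n_skipped``; rows with an
    unparseable optional charge keep the peak with charge absent.  When
    only m/z and charge are mapped the neutral mass is computed on demand
    by :attr:`Peak.neutral_mass`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if run_id is None:
        run_id = path.stem

    frame = pd.read_csv(path, sep=mapping.delimiter, dtype=str, comment=None)
    missing = [
        col for col in mapping.columns.values() if col not in frame.columns
    ]
    if missing:
        raise PeakListError(
            f"{path.name}: mapped column(s) {missing} absent from header "
            f"{list(frame.columns)}"
        )

    peaks: list[Peak] = []
    n_skipped = 0
    cols = mapping.columns
    rt_scale = 1.0 / 60.0 if mapping.rt_units == "seconds" else 1.0
    for row in frame.itertuples(index=False):
        rec = dict(zip(frame.columns, row))
        mz = _coerce_float(rec[cols["mz"]]) if "mz" in cols else None
        mass = _coerce_float(rec[cols["mass"]]) if "mass" in cols else None
        rt = _coerce_float(rec[cols["rt"]])
        intensity = _coerce_float(rec[cols["intensity"]])
        charge = _coerce_int(rec[cols["charge"]]) if "charge" in cols else None
        scan = _coerce_int(rec[cols["scan"]]) if "scan" in cols else None
        if rt is None or intensity is None or (mz is None and mass is None):
            n_skipped += 1
            continue
        if charge is not None and charge < 1:
            charge = None
        if mz is None:
            # mass-only input: synthesise a singly-protonated m/z so the
            # Peak invariants hold; matching downstream uses mass anyway.
            mz = mass_to_mz(mass, charge or 1)
        try:
            peaks.append(
                Peak(
                    run_id=run_id,
                    mz=mz,
                    rt=rt * rt_scale,
                    intensity=intensity,
                    charge=charge,
                    mass=mass,
                    scan=scan,
                )
            )
        except PeakListError as exc:
            logger.debug("skipping row in %s: %s", path.name, exc)
            n_skipped += 1

    if not peaks:
        logger.warning("%s: no parseable peaks", path.name)
    if n_skipped:
        logger.info("%s: skipped %d malformed row(s)", path.name, n_skipped)
    return PeakList(
        run_id=run_id,
        condition=condition,
        replicate=replicate,
        peaks=peaks,
        n_skipped=n_skipped,
    )


def write_peaklist(peaklist: PeakList, path) -> None:
    """Write a peak list as a simple TSV (mz, charge, mass, rt, intensity)."""
    rows = [
        {
            "mz": p.mz,
            "charge": "" if p.charge is None else p.charge,
            "mass": "" if p.mass is None else p.mass,
            "rt": p.rt,
            "intensity": p.intensity,
        }
        for p in peaklist.peaks
    ]
    pd.DataFrame(
        rows, columns=["mz", "charge", "mass", "rt", "intensity"]
    ).to_csv(path, sep="\t", index=False)


#: Default filename pattern for batch loading: e.g. ``untreated_rep2.tsv``.
DEFAULT_FILENAME_PATTERN = (
    r"(?P<condition>untreated|ap_treated)_rep(?P<replicate>[1-6])"
)


def load_directory(
    directory,
    mapping: ColumnMapping = SIMPLE_MAPPING,
    file_glob: str = "*.tsv",
    filename_pattern: str = DEFAULT_FILENAME_PATTERN,
) -> dict[int, dict[str, PeakList]]:
    """Batch-load every peak list under ``directory``.

    Condition and replicate are inferred from each filename via a regex
    with named groups ``condition`` and ``replicate``.  Returns a nested
    mapping ``{replicate: {condition: PeakList}}``.  Files not matching
    the pattern are ignored with a log entry.
    """
    directory = Path(directory)
    pattern = re.compile(filename_pattern)
    out: dict[int, dict[str, PeakList]] = {}
    for path in sorted(directory.glob(file_glob)):
        m = pattern.search(path.stem)
        if m is None:
            logger.info("ignoring %s: no condition/replicate in name", path.name)
            continue
        condition = m.group("condition")
        replicate = int(m.group("replicate"))
        pl = read_peaklist(path, mapping, condition=condition, replicate=replicate)
        out.setdefault(replicate, {})[condition] = pl
    return out


def expand_globs(patterns: Sequence[str]) -> list[str]:
    """Expand shell globs to a sorted list of existing paths."""
    paths: list[str] = []
    for pat in patterns:
        hits = sorted(_glob.glob(pat))
        paths.extend(hits if hits else ([pat] if Path(pat).exists() else []))
    return paths
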