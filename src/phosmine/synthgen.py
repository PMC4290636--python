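"""Deterministic synthetic LC-MS data with planted phosphopeptides.

Emulates the statistical structure of an alkaline-phosphatase paired
experiment: a set of phosphopeptides whose features appear in the
untreated runs at neutral mass M and in the AP-treated runs at
M - n x 79.966 Da (n phosphate groups), embedded among abundant
background ("decoy") features that do not shift.  Peptide identification
and label-free quantification tables consistent with the planted truth
are generated for the downstream linking stage.

All randomness flows through one seeded ``numpy.random.Generator``; a
fixed seed reproduces every output byte-for-byte.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .peaklists import (
    AP_TREATED,
    PHOSPHO_MASS,
    UNTREATED,
    Peak,
    PeakList,
    mass_to_mz,
    write_peaklist,
)

_AMINO_ACIDS = "ACDEFGHIKLMNPQRVW"  # S/T/Y inserted explicitly at sites


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition parameters of the simulator.

    Defaults model a pTyr-enriched tryptic digest measured by nano-LC
    Orbitrap MS: peptide masses 800-3500 Da (full-scan m/z 300-2000 at
    charges 1-3), elution between 10 and 60 min, lognormal feature
    intensities, mostly singly-phosphorylated peptides, complete
    dephosphorylation by the phosphatase, three replicate pairs.
    """

    n_phospho: int = 20
    n_decoys: int = 200
    mods_distribution: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.60, 2: 0.25, 3: 0.09, 4: 0.04, 5: 0.02}
    )
    mass_noise_sd: float = 0.005
    rt_noise_sd: float = 0.3
    rt_range: tuple[float, float] = (10.0, 60.0)
    mass_range: tuple[float, float] = (800.0, 3500.0)
    charge_distribution: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.7, 3: 0.3}
    )
    decoy_charge_distribution: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.1, 2: 0.6, 3: 0.3}
    )
    intensity_lognormal: tuple[float, float] = (14.0, 1.0)
    dephospho_efficiency: float = 1.0
    n_replicates: int = 3
    residue_weights: Mapping[str, float] = field(
        default_factory=lambda: {"S": 0.2, "T": 0.2, "Y": 0.6}
    )
    fold_changes: Optional[Sequence[float]] = None
    delta_mass: float = PHOSPHO_MASS
    decoy_guard: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for dist, name in (
            (self.mods_distribution, "mods_distribution"),
            (self.charge_distribution, "charge_distribution"),
            (self.decoy_charge_distribution, "decoy_charge_distribution"),
            (self.residue_weights, "residue_weights"),
        ):
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities sum to {total}, not 1")
        if self.mass_noise_sd < 0 or self.rt_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not 0 <= self.dephospho_efficiency <= 1:
            raise ValueError("dephospho_efficiency must be in [0, 1]")
        if not 1 <= self.n_replicates <= 6:
            raise ValueError("n_replicates must be in 1..6")
        if self.fold_changes is not None and len(self.fold_changes) != self.n_phospho:
            raise ValueError("fold_changes length must equal n_phospho")


@dataclass
class PlantedPeptide:
    """Ground truth for one planted phosphopeptide."""

    peptide_id: str
    sequence: str
    residue: str
    site_position: int
    mass: float  # neutral mass of the phosphorylated form
    rt: float
    n_mods: int
    charge: int
    base_intensity: float
    fold_change: float
    present_untreated: list[bool]
    present_treated: list[bool]


@dataclass
class GroundTruth:
    peptides: list[PlantedPeptide]

    def __len__(self) -> int:
        return len(self.peptides)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "peptide_id": p.peptide_id,
                    "sequence": p.sequence,
                    "residue": p.residue,
                    "site_position": p.site_position,
                    "mass": p.mass,
                    "rt": p.rt,
                    "n_mods": p.n_mods,
                    "charge": p.charge,
                    "base_intensity": p.base_intensity,
                    "fold_change": p.fold_change,
                    "present_untreated": ";".join(
                        "1" if b else "0" for b in p.present_untreated
                    ),
                    "present_treated": ";".join(
                        "1" if b else "0" for b in p.present_treated
                    ),
                }
                for p in self.peptides
            ]
        )


def _draw(rng: np.random.Generator, dist: Mapping) -> object:
    keys = list(dist.keys())
    probs = np.array([dist[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _random_sequence(
    rng: np.random.Generator, residue: str, length: int = 12
) -> tuple[str, int]:
    """Tryptic-looking sequence with the phospho residue planted inside."""
    body = "".join(rng.choice(list(_AMINO_ACIDS), size=length - 2))
    pos = int(rng.integers(1, length - 1))  # keep off both termini
    seq = body[: pos - 1] + residue + body[pos - 1 :] + rng.choice(["K", "R"])
    return seq, pos


def _shift_safe(
    mass: float, existing: Sequence[float], delta: float, max_mods: int, guard: float
) -> bool:
    """True when ``mass`` cannot form a spurious n*delta pair with ``existing``."""
    for other in existing:
        diff = abs(mass - other)
        for n in range(1, max_mods + 1):
            if abs(diff - n * delta) < guard:
                return False
    return True


def generate_pairs(
    config: SynthConfig,
) -> tuple[list[tuple[PeakList, PeakList]], GroundTruth]:
    """Generate paired untreated/AP-treated peak lists plus ground truth.

    Planted phosphopeptides appear in every untreated replicate at their
    phosphorylated mass and in each treated replicate (with probability
    ``dephospho_efficiency``) at mass − n_mods x delta_mass, both with
    Gaussian mass and RT jitter.  Decoys are rejection-sampled so no
    decoy-involved mass difference falls within ``decoy_guard`` of any
    n x delta_mass, guaranteeing zero spurious pairs at tolerances below
    the guard.
    """
    rng = np.random.default_rng(config.seed)
    lo_rt, hi_rt = config.rt_range
    lo_m, hi_m = config.mass_range
    mu_i, sd_i = config.intensity_lognormal

    peptides: list[PlantedPeptide] = []
    planted_masses: list[float] = []
    for i in range(config.n_phospho):
        residue = str(_draw(rng, config.residue_weights))
        seq, pos = _random_sequence(rng, residue)
        n_mods = int(_draw(rng, config.mods_distribution))
        # keep planted masses mutually shift-safe so distinct planted
        # peptides cannot cross-pair
        for _ in range(1000):
            mass = float(rng.uniform(lo_m, hi_m))
            probe = [mass - n_mods * config.delta_mass, mass]
            if all(
                _shift_safe(m, planted_masses, config.delta_mass,
                            len(config.mods_distribution), config.decoy_guard)
                for m in probe
            ):
                break
        planted_masses.extend([mass, mass - n_mods * config.delta_mass])
        fold = (
            config.fold_changes[i]
            if config.fold_changes is not None
            else 1.0
        )
        peptides.append(
            PlantedPeptide(
                peptide_id=f"P{i:03d}",
                sequence=seq,
                residue=residue,
                site_position=pos,
                mass=mass,
                rt=float(rng.uniform(lo_rt + 1, hi_rt - 1)),
                n_mods=n_mods,
                charge=int(_draw(rng, config.charge_distribution)),
                base_intensity=float(rng.lognormal(mu_i, sd_i)),
                fold_change=float(fold),
                present_untreated=[True] * config.n_replicates,
                present_treated=[
                    bool(rng.random() < config.dephospho_efficiency)
                    for _ in range(config.n_replicates)
                ],
            )
        )

    max_mods = len(config.mods_distribution)
    decoys: list[tuple[float, float, int, float]] = []  # mass, rt, charge, inten
    all_masses = list(planted_masses)
    for _ in range(config.n_decoys):
        for _ in range(1000):
            mass = float(rng.uniform(lo_m, hi_m))
            if _shift_safe(
                mass, all_masses, config.delta_mass, max_mods, config.decoy_guard
            ):
                break
        all_masses.append(mass)
        decoys.append(
            (
                mass,
                float(rng.uniform(lo_rt, hi_rt)),
                int(_draw(rng, config.decoy_charge_distribution)),
                float(rng.lognormal(mu_i, sd_i)),
            )
        )

    replicates: list[tuple[PeakList, PeakList]] = []
    for rep in range(1, config.n_replicates + 1):
        u_id = f"untreated_rep{rep}"
        t_id = f"ap_treated_rep{rep}"
        u_peaks: list[Peak] = []
        t_peaks: list[Peak] = []
        for p in peptides:
            if p.present_untreated[rep - 1]:
                m = p.mass + rng.normal(0, config.mass_noise_sd * p.charge)
                u_peaks.append(
                    Peak(
                        run_id=u_id,
                        mz=mass_to_mz(m, p.charge),
                        charge=p.charge,
                        mass=m,
                        rt=max(0.0, p.rt + rng.normal(0, config.rt_noise_sd)),
                        intensity=p.base_intensity
                        * float(rng.lognormal(0, 0.05)),
                    )
                )
            if p.present_treated[rep - 1]:
                m = (
                    p.mass
                    - p.n_mods * config.delta_mass
                    + rng.normal(0, config.mass_noise_sd * p.charge)
                )
                t_peaks.append(
                    Peak(
                        run_id=t_id,
                        mz=mass_to_mz(m, p.charge),
                        charge=p.charge,
                        mass=m,
                        rt=max(0.0, p.rt + rng.normal(0, config.rt_noise_sd)),
                        intensity=p.base_intensity
                        * float(rng.lognormal(0, 0.05)),
                    )
                )
        for mass, rt, charge, inten in decoys:
            for peaks, run in ((u_peaks, u_id), (t_peaks, t_id)):
                m = mass + rng.normal(0, config.mass_noise_sd * charge)
                peaks.append(
                    Peak(
                        run_id=run,
                        mz=mass_to_mz(m, charge),
                        charge=charge,
                        mass=m,
                        rt=max(0.0, rt + rng.normal(0, config.rt_noise_sd)),
                        intensity=inten * float(rng.lognormal(0, 0.05)),
                    )
                )
        u_peaks.sort(key=lambda p: (p.rt, p.mz))
        t_peaks.sort(key=lambda p: (p.rt, p.mz))
        replicates.append(
            (
                PeakList(u_id, UNTREATED, rep, u_peaks),
                PeakList(t_id, AP_TREATED, rep, t_peaks),
            )
        )
    return replicates, GroundTruth(peptides)


def generate_id_quant(
    config: SynthConfig,
    truth: GroundTruth,
    id_fraction: float = 1.0,
    score_mean: float = 40.0,
    score_sd: float = 5.0,
    quant_noise_sd: float = 0.05,
    n_quant_runs: int = 3,
    seed_offset: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit identification and quantification tables for planted peptides.

    The id table follows the Mascot-style CSV consumed by the linker
    (pep_seq, pep_var_mod, pep_exp_mz, pep_exp_z, pep_rt, pep_score,
    prot_acc).  The quant table carries feature m/z, rt, charge and one
    abundance column per run (control_1..n, treatment_1..n) whose group
    means realise each peptide's planted control/treatment fold change
    under lognormal noise.
    """
    rng = np.random.default_rng(config.seed + seed_offset)
    id_rows = []
    quant_rows = []
    for p in truth.peptides:
        mz = mass_to_mz(p.mass, p.charge)
        if rng.random() <= id_fraction:
            score = float(rng.normal(score_mean, score_sd))
            id_rows.append(
                {
                    "prot_acc": f"SYN_{p.peptide_id}",
                    "pep_seq": p.sequence,
                    "pep_var_mod": (
                        f"Phospho ({p.residue}): "
                        f"p{p.residue}{p.site_position}"
                    ),
                    "pep_exp_mz": round(mz + rng.normal(0, 0.002), 4),
                    "pep_exp_z": p.charge,
                    "pep_rt": round(p.rt + rng.normal(0, 0.2), 3),
                    "pep_score": round(score, 1),
                }
            )
        # control mean = base, treatment mean = base / fold_change
        row = {
            "feature_id": f"F_{p.peptide_id}",
            "mz": round(mz + rng.normal(0, 0.002), 4),
            "rt": round(p.rt + rng.normal(0, 0.2), 3),
            "charge": p.charge,
        }
        base = p.base_intensity
        treat = base / p.fold_change if np.isfinite(p.fold_change) and p.fold_change > 0 else 0.0
        for r in range(1, n_quant_runs + 1):
            row[f"control_{r}"] = round(
                base * float(rng.lognormal(0, quant_noise_sd)), 1
            )
            row[f"treatment_{r}"] = round(
                treat * float(rng.lognormal(0, quant_noise_sd)), 1
            ) if treat > 0 else 0.0
        quant_rows.append(row)
    id_frame = pd.DataFrame(
        id_rows,
        columns=[
            "prot_acc", "pep_seq", "pep_var_mod", "pep_exp_mz",
            "pep_exp_z", "pep_rt", "pep_score",
        ],
    )
    quant_cols = ["feature_id", "mz", "rt", "charge"] + [
        f"{cond}_{r}"
        for r in range(1, n_quant_runs + 1)
        for cond in ("control", "treatment")
    ]
    quant_frame = pd.DataFrame(quant_rows, columns=quant_cols)
    return id_frame, quant_frame


def default_run_conditions(n_quant_runs: int = 3) -> dict[str, str]:
    """Run-column -> condition map matching :func:`generate_id_quant` output."""
    out = {}
    for r in range(1, n_quant_runs + 1):
        out[f"control_{r}"] = "control"
        out[f"treatment_{r}"] = "treatment"
    return out


def write_dataset(config: SynthConfig, out_dir) -> dict[str, list[str]]:
    """Generate and write the full dataset (peak lists, ids, quant, truth)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    replicates, truth = generate_pairs(config)
    id_frame, quant_frame = generate_id_quant(config, truth)
    written: dict[str, list[str]] = {"peaklists": [], "tables": []}
    for u, t in replicates:
        for pl in (u, t):
            path = out_dir / f"{pl.run_id}.tsv"
            write_peaklist(pl, path)
            written["peaklists"].append(str(path))
    id_path = out_dir / "identifications.csv"
    quant_path = out_dir / "quantification.csv"
    truth_path = out_dir / "ground_truth.tsv"
    id_frame.to_csv(id_path, index=False)
    quant_frame.to_csv(quant_path, index=False)
    truth.to_frame().to_csv(truth_path, sep="\t", index=False)
    written["tables"] = [str(id_path), str(quant_path), str(truth_path)]
    return written
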