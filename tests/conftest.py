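import numpy as np
import pytest

from phosmine import (
    AP_TREATED,
    UNTREATED,
    MinerParams,
    Peak,
    PeakList,
    SynthConfig,
    generate_pairs,
    mass_to_mz,
)


def make_peak(
    mass=None,
    mz=None,
    charge=2,
    rt=20.0,
    intensity=1e6,
    run_id="run",
):
    """Peak constructor for tests: specify mass or mz, the other derives."""
    if mass is not None and mz is None:
        mz = mass_to_mz(mass, charge or 1)
    return Peak(
        run_id=run_id,
        mz=mz,
        charge=charge,
        mass=mass,
        rt=rt,
        intensity=intensity,
    )


def make_list(peaks, condition=UNTREATED, replicate=1, run_id="run"):
    import dataclasses

    peaks = [
        p if p.run_id == run_id else dataclasses.replace(p, run_id=run_id)
        for p in peaks
    ]
    return PeakList(
        run_id=run_id, condition=condition, replicate=replicate, peaks=peaks
    )


def random_peaklists(rng, n_untreated=50, n_treated=50):
    """Unstructured random peak lists for oracle-equivalence checks."""
    def peaks(n, run):
        out = []
        for _ in range(n):
            mass = float(rng.uniform(800, 2000))
            charge = int(rng.integers(2, 4))
            out.append(
                Peak(
                    run_id=run,
                    mz=mass_to_mz(mass, charge),
                    charge=charge,
                    mass=mass,
                    rt=float(rng.uniform(0, 60)),
                    intensity=float(rng.uniform(1e3, 1e7)),
                )
            )
        return out

    u = make_list(peaks(n_untreated, "u"), UNTREATED, 1, "u")
    t = make_list(peaks(n_treated, "t"), AP_TREATED, 1, "t")
    return u, t


def mine_pair_oracle(untreated, treated, params):
    """Exhaustive (u, t, n) triple enumeration; definitional reference
    for the sort-and-window miner."""
    from phosmine.shiftminer import ShiftCandidate

    out = []
    for u in untreated:
        mu = u.neutral_mass
        if mu is None:
            continue
        for n in range(1, params.max_mods + 1):
            best = None
            for t in treated:
                mt = t.neutral_mass
                if mt is None:
                    continue
                mass_error = (mu - mt) - n * params.delta_mass
                rt_diff = u.rt - t.rt
                if abs(mass_error) > params.mass_tol:
                    continue
                if abs(rt_diff) > params.rt_tol:
                    continue
                if params.require_same_charge and u.charge != t.charge:
                    continue
                key = (abs(mass_error), abs(rt_diff))
                if best is None or key < best[0]:
                    best = (key, t, mass_error, rt_diff)
            if best is not None:
                out.append(
                    ShiftCandidate(
                        untreated_peak=u,
                        treated_peak=best[1],
                        n_mods=n,
                        mass_error=best[2],
                        rt_diff=best[3],
                        replicate=untreated.replicate,
                    )
                )
    return out


def candidate_key(c):
    return (
        round(c.untreated_peak.mz, 6),
        round(c.treated_peak.mz, 6),
        c.n_mods,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def clean_dataset():
    """Low-noise synthetic dataset: noise well under half of every
    mining tolerance, so perfect recovery is expected."""
    config = SynthConfig(seed=7)
    replicates, truth = generate_pairs(config)
    return config, replicates, truth


@pytest.fixture
def default_params():
    return MinerParams()
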