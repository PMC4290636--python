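"""Neutral-mass arithmetic and mining of a single known phosphopeptide pair.

A pTyr peptide is observed at m/z 812.858 (2+) in the untreated run and,
after alkaline-phosphatase treatment, at m/z 772.870 (2+).  The neutral
masses differ by one phosphate group (HPO3, 79.966 Da), which is exactly
the signature the miner looks for.
"""

from phosmine import (
    AP_TREATED,
    UNTREATED,
    MinerParams,
    Peak,
    PeakList,
    compute_neutral_mass,
    mine_pair,
    round_mz,
)

m_untreated = compute_neutral_mass(812.858, 2)
m_treated = compute_neutral_mass(772.870, 2)
print(f"untreated neutral mass : {m_untreated:.3f} Da (m/z 812.858, 2+)")
print(f"treated   neutral mass : {m_treated:.3f} Da (m/z 772.870, 2+)")
print(f"observed mass shift    : {m_untreated - m_treated:.3f} Da "
      f"(one HPO3 = 79.966 Da)")

untreated = PeakList("u", UNTREATED, 1,
                     [Peak("u", mz=812.858, charge=2, rt=24.1, intensity=1e6)])
treated = PeakList("t", AP_TREATED, 1,
                   [Peak("t", mz=772.870, charge=2, rt=23.5, intensity=1e6)])
(cand,) = mine_pair(untreated, treated, MinerParams())
print(f"mined candidate        : n_mods={cand.n_mods}, "
      f"mass_error={cand.mass_error:+.3f} Da, rt_diff={cand.rt_diff:+.1f} min")
print(f"inclusion-list m/z     : {round_mz(812.8579, 2)}")
# The 0.010 Da mass error is well inside the default 0.05 Da tolerance,
# so this pair is accepted as a single-phosphate candidate.
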