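# Methods

## Model

The pipeline rests on one chemical fact: alkaline phosphatase removes
phosphate groups from phosphopeptides, and each removal lowers the
neutral monoisotopic mass by the HPO₃ mass, Δφ = 79.966 Da.  For a
peptide observed at mass-to-charge *m/z* with charge *z*, the neutral
mass is

    M = z·(m/z) − z·m_p,    m_p = 1.00728 Da.

The proton mass is deliberately fixed at five decimals rather than the
CODATA value (1.0072765 Da): at the charge states and mass tolerances of
this workflow the difference (< 0.2 mDa at z ≤ 3) is immaterial, and the
rounded constant reproduces tabulated worked masses to three decimals.
It is exposed as `phosmine.PROTON_MASS` and cross-checked against
pyteomics in the test suite.

A candidate phosphopeptide is a pair (u, t) of features from an
untreated and an AP-treated run of the same replicate with

    |(M_u − M_t) − n·Δφ| ≤ tol_mass   and   |RT_u − RT_t| ≤ tol_RT

for some phosphate count n ∈ {1…max_mods}.  Matching is on neutral mass,
not raw m/z, so the partners may carry different charge states (the
phosphatase does not preserve ionisation behaviour); a
`require_same_charge` switch restores strict matching for instruments
where charge is reliably reproducible.

## Mining parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `delta_mass` | 79.966 | Da | HPO₃ monoisotopic mass; user-settable so other mass-shifting treatments can be mined |
| `mass_tol` | 0.05 | Da | matches high-resolution Orbitrap survey-scan accuracy with margin |
| `rt_tol` | 5 | min | dephosphorylated peptides elute earlier/later by up to a few minutes on C18 |
| `max_mods` | 5 | — | multiply-phosphorylated tryptic peptides beyond 5 sites are rare |
| `min_charge` | 2 | — | singly-charged features are dominated by chemical noise |
| `top_n` | 3000 | peaks | intensity cut against noise peaks; `"auto"` uses the knee heuristic |

The knee heuristic sorts intensities descending and cuts immediately
before the largest drop between consecutive values ("greatest slope
change"), ties resolved toward the smaller N.  It is advisory: the
chart data (`intensity_chart_data`) is exposed so an operator can pick N
visually, and `top_n` stays user-settable.  Filters apply in the order
charge → intensity floor → top-N truncation, with intensity ties broken
by ascending m/z for determinism.

When one untreated peak matches several treated peaks at the same n, the
match with the smallest |mass error| (then smallest |RT difference|)
wins — unconstrained many-to-many emission inflates the candidate list
combinatorially without adding targets.  A peak may legitimately appear
at several distinct n (multiply-phosphorylated forms); deduplication
happens at the inclusion-list stage.  The production miner sorts the
treated list by mass and scans a binary-search window per (u, n); its
contract, enforced by tests, is exact agreement with the quadratic
enumeration of every (u, t, n) triple.

Replicate merging clusters candidates greedily on the untreated peak's
(m/z, RT), seeded in descending intensity order (0.02 Th / 2 min
defaults), keeps the highest-intensity member as representative, and
records per-cluster support = number of distinct replicates.
`min_support` defaults to 1: requiring presence in all replicates is a
stricter intersection rule an operator can opt into.

## Inclusion lists

Candidates collapse on their untreated m/z rounded to `round_decimals`
(default 2) — rounding is half-away-from-zero via decimal arithmetic
(812.8579 → 812.86, 1.005 → 1.01), with banker's rounding available since
instrument software differs.  The elution range (default 10–60 min) is
split into `n_segments` (default 10) half-open equal segments, the last
closed; a merged target is assigned by the median of its member RTs
(robust to one aberrant replicate) and out-of-range targets are clamped
to the nearest segment with a log entry.

Two window modes are provided because instrument methods accept either:
`segment` pads the segment bounds by `extra_rt_tol` (a 5-min segment with
1.5-min padding gives an 8-min window); `candidate_extent` (default) pads
the observed RT extent of the member candidates, which produces tighter,
per-target windows (e.g. members at 23.01 and 26.93 min → 21.51–28.43).
An optional per-segment capacity cap respects instrument list limits.

## Linking identifications to quantification

Identifications below `min_score` (default 25) or carrying no
phosphosite of the requested residue types are removed, then each is
assigned to the quantification feature minimizing |Δm/z| (then |ΔRT|)
within 0.2 Th / 2 min and, by default, of equal charge.  One-to-one best
matching is the default; `keep_all_matches` emits every qualifying
feature for manual review.  The abundance ratio is
mean(control)/mean(treatment), with an `infinity` sentinel when the
treatment group is entirely zero (a real outcome for peptides abolished
by treatment) and NaN for 0/0.  Significance is one-way ANOVA
(`scipy.stats.f_oneway`) across condition groups; fewer than two runs in
any group yields no p-value and the row is retained unflagged.  When all
abundances are identical the ANOVA statistic is undefined and p is
reported as 1 (no evidence of any effect).

The localization delta score of a peptide sequence is the top ion score
minus the second among its alternative phosphosite placements; a single
placement has no competitor and returns the top score itself (documented
convention — the quantity is then a lower bound on localization
confidence rather than a contrast).

The modification-string dialect expects phosphosites as `pS#`/`pT#`/`pY#`
tokens with 1-based positions (e.g. `"2 Phospho (ST): pT2, pS5"`); other
modifications are ignored, and a site disagreeing with the sequence
excludes the row with a log entry rather than silently mislabelling it.

## Synthetic data

`SynthConfig` plants `n_phospho` (20) phosphopeptides among `n_decoys`
(200) background peaks per run, over `n_replicates` (3) untreated/treated
pairs.  Masses are uniform in 800–3500 Da (the tryptic range visible at
m/z 300–2000 for charges 1–3), RTs uniform in 10–60 min, intensities
lognormal(μ=14, σ=1), charges 2:3 at 70:30 for planted peptides (decoys
include 10% singly-charged, which the default charge filter removes),
phosphate counts mostly 1 (60%) with a tail to 5, and mass/RT jitter of
0.005 Th·z / 0.3 min — half of the corresponding matching tolerances, so
recovery should be complete.  `dephospho_efficiency` < 1 models
incomplete phosphatase digestion.  Decoys are rejection-sampled so that
no decoy-involved mass difference falls within 0.1 Da (twice the mass
tolerance) of any n·Δφ, making "zero decoy pairs" a well-defined
expectation rather than a probabilistic one; planted masses are sampled
under the same guard against each other.  Identification scores are
normal (default mean 40, sd 5) and quantification abundances realise
per-peptide control/treatment fold changes under lognormal noise.

What the generator does **not** emulate: isotope envelopes and
deconvolution errors, correlated RT drift between runs, intensity-
dependent mass error, missing values in quantification, co-eluting
near-isobaric interference, and fragment spectra.  Passing tests
therefore demonstrate the correctness of the matching, segmentation and
linking logic under the stated noise model — not robustness to raw-data
pathologies, which live upstream of this package's inputs (peak
detection and search are external).

## Numerical and design choices

- Retention time is canonically minutes; seconds-based exports
  (msInspect) convert on load via the column mapping.
- Malformed peak-list rows are skipped and counted, never fatal;
  instrument exports routinely contain footer junk.  Rows lacking charge
  are kept (they still match by mass if a mass column exists) but are
  dropped by any filter with `min_charge` > 1.
- All tie-breaks (intensity ranking, best-match selection, cluster
  seeding) are total orders, so every stage is bit-deterministic for
  identical inputs; the CLI writes a manifest (parameters, input SHA-256
  digests, version) with every output.
- Problem sizes in the test and acceptance runs (instances up to 200×200
  peaks, 50 random oracle instances, 10 recovery seeds, 1,000-precursor
  partition checks) were chosen as the smallest scales at which the
  properties under test are non-trivial while keeping the suite fast to
  iterate on.

## Known limitations

- Candidate pairs carry no false-discovery-rate estimate; the mass-shift
  criterion is a screen, and confidence comes from the downstream MS/MS
  identification.
- Replicate merging is greedy single-linkage; pathological candidate
  chains spaced just under the cluster tolerance can bridge distinct
  targets (mitigated by intensity-ordered seeding).
- The equal-segment inclusion layout does not balance targets per
  segment; dense elution regions may exceed instrument capacity unless
  `max_per_segment` is set.
- The Mascot-style modification dialect is the only one implemented;
  other engines' exports need pre-mapping to it.
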