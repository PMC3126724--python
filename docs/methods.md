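# Methods

## Melting-temperature model and calibration

`bstag.thermo.melt_temp` uses the unified nearest-neighbor parameter set
with the entropic monovalent-salt correction (0.368·(N−1)·ln[Na⁺]) and the
standard divalent adjustment (effective [Na⁺] = [Na⁺] + 120·√([Mg²⁺] − [dNTP]) in
mM), as implemented in Biopython's `MeltingTemp.Tm_NN`.  Duplex
concentration uses the probe concentration alone (excess-template
asymmetric PCR regime, complementary strand at zero).

The tag system's reference Tm values were published without buffer
conditions, so the conditions are *fitted*, not assumed:
`calibrate_conditions` exhaustively searches a documented grid of standard
values — Na⁺ ∈ {20, 50, 75, 100, 150} mM, Mg²⁺ ∈ {0…3} mM in 0.5 mM steps,
oligo ∈ {50, 100, 200, 250, 500} nM, dNTP ∈ {0, 0.2, 0.8} mM — and keeps the
point minimizing the maximum absolute residual over the supplied
(sequence, Tm) table.  On the shipped six-tag table the optimum
(Na⁺ 50 mM, Mg²⁺ 1.5 mM, oligo 200 nM, dNTP 0.2 mM) leaves a maximum
residual of 0.023 °C; every tag rounds to its reported value at 0.1 °C
precision (round-half-up, the reporting convention throughout).  These
conditions ship as `CALIBRATED_CONDITIONS`.  Calibration is deterministic
(fixed grid order, strict-improvement updates); a table no grid point can
fit within tolerance returns a failure *report* carrying the best residuals
rather than raising.

## Positional duplex model

Cross-annealing between tags is judged positionally, not with
mismatch-specific NN free energies: the design argument for the split tag is
positional (sub-sequences of ≤ 7 nt do not prime; a 3'-proximal mismatch
blocks extension), and mismatch NN parameters would suggest a precision the
rule-based gate does not need.  `duplex_score` compares a probe base-by-base
against the reverse complement of its template site and reports mismatch
positions, the longest perfect run, the perfect run anchored at the probe
3' terminus, and a weighted score with 3'-proximity weights (3 for the
3'-terminal 3 positions, 2 for positions 4–8 from the 3' end, 1 elsewhere;
configurable).  `anneals` passes iff (i) the longest perfectly matched
sub-duplex, melted as an independent short duplex, reaches the annealing
temperature minus a 3 °C margin, and (ii) the 3'-anchored run is at least 8
nt with at most 2 mismatches overall.  The margin keeps the lowest-melting
shipped tag (47.2 °C) primable at the 49 °C labeling step; the 8-nt seed is
one more than the non-priming split length.

## Tag-set policy and generation

The pair rule is **bar-code uniqueness plus a weighted-score floor of 3**
(one bar-code mismatch at full 3' weight).  A stricter literal rule —
"pairs must differ at the split base *and* the bar-code" — would reject
pairs within the shipped set itself (F9GAC/F9TAC share split base C), so
consistency with the published set was preferred over the prose rule.

`generate_tagset` enumerates the full candidate space (4 split bases × 32
GC-clamped bar-codes = 128), filters by the single-tag rules (GC clamp, Tm
window 46–53 °C bracketing the shipped set), and selects a size-k subset
maximizing the minimum pairwise weighted score.  Selection is exact:
descending threshold search with lexicographic clique backtracking, which
returns the lexicographically first optimum (verified against brute-force
subset enumeration on reduced pools).  A greedy max-min fallback exists only
for budget exhaustion at large k.  There is no randomness anywhere in the
path; two runs are byte-identical.

## Mispriming screen

`find_priming_sites` requires an exact match of the primer's 3'-terminal
8-mer (seed) and at most 2 mismatches over the full footprint, both strands,
N never matching.  This replaces a sequence-similarity search plus empirical
annealing gradient with the PCR-relevant question — can the 3' end land
perfectly and the rest hold — and is checked against a brute-force
all-positions scanner in the tests.  Amplicons pair converging
opposite-strand sites within 2000 bp.  The (seed, mismatch) ↔
annealing-stringency mapping is a modeling choice and is stamped into every
report header.  Screens run on synthetic uniform-composition backgrounds
(12 × 20 kb by default, mirroring the twelve plant species of the original
no-amplification screen); passing there validates the scanner, not any real
genome — real backgrounds can be supplied as FASTA.

## SSR and SNP assay rules

SSR/indel assembly prepends the tag to the forward core and the lowercase
`gtttctt` PIG-tail to the reverse core (the tail promotes uniform
non-templated adenylation; it is reproduced verbatim as a configurable
constant).  The **Tm-gap rule** — core forward Tm at least 6 °C above the
tag Tm — is a hard error, because assays below the gap amplified too weakly
in practice (5 of 201 markers failed this way).  The shipped demonstration
assays clear it with a minimum gap of 7.3 °C.

ASO design: the allele-specific core ends at the SNP base (3' base = allele)
and is extended 5' until it clears a 55 °C core-Tm floor and the GC-run rule
(no G/C stretch > 5).  A template G or C at offset 1–6 upstream of the SNP
base — smallest offset first — is replaced by its transversion partner
(G→T, C→A, configurable; rendered lowercase) to destabilize
mishybridization of the wrong allele.  The second allele's core takes one
extra 5'-template base so tagged lengths differ by exactly 1 bp (stagger at
the 5' end, never by trimming the 3' end), separating alleles by size as
well as dye.  The LSO is a pigtailed reverse-orientation primer on the
downstream flank (20 bp gap by default).  Offsets count upstream of the SNP
base, which is excluded: the printed assays' lowercase mismatch sits at
offset 1 under this convention.  `validate_snp_assay` checks every
template-free invariant; the *identity* of the replaced base is not judged,
because without the genomic template a lowercase base cannot be proven to be
a replacement (one shipped assay's lowercase "c" could not have arisen from
the documented G/C→T/A rule, so position and annotation are what the
validator owns).

## Panels and the labeling simulation

Apparent size = product length + 16 (tag) + per-dye mobility offset.
Default offsets (6-FAM −3, VIC −2, NED −1, PET +1) are placeholders spanning
the observed 13–17 bp aggregate shift; the decomposition between tag and dye
was never published, so calibrate per instrument.  Panel invariants: unique
tags, ≤ 6 assays per tube, same-dye apparent-size windows separated by a
10 bp guard band (no published value; chosen to exceed typical SSR allele
steps).  `build_panel` is deterministic backtracking preferring unused dyes;
infeasibility diagnoses name a conflict set minimal in the sense that
removing any one member restores feasibility.  `dye_swap` re-validates and
fails atomically.

The simulation is rule-based, not kinetic.  Stage 1: a pool of tagged
single-stranded product forms if the core primer anneals at the stage-1
temperature; a labeled tag primer whose Tm reaches that temperature
triggers a warning (the gap rule exists to prevent exactly that).  Stage 2
(3 cycles at 49 °C): every (labeled tag primer, pool) pair emits peaks iff
the tag duplex passes `anneals` — a matched tag always does, any shipped
cross pair never does, which yields the exclusivity and
no-peak-on-mismatch behavior the tests fuzz over 200 random panels.

`labeling_yield` models the plateau: per cycle, labeled product increases by
min(conversion × remaining ss template, remaining labeled primer), defaults
template 1.0, primer 0.85, conversion 0.4 (arbitrary units).  The curve is
non-decreasing and concave with the fourth-cycle increment < 20 % of the
first — the observed "proportional to three cycles, plateau at four" shape.
Absolute fluorescence intensities are out of scope.

## Synthetic data

`bstag.fixtures` generates uniform-composition random backgrounds
(deterministic per seed, byte-identical files) and plants explicit primer
sites, SSR loci (allele 0 planted; all allele product lengths recorded in
the truth table), and SNP contexts.  It emulates the *geometry* of real
screening substrates — planted binding sites at known coordinates — not
their composition bias, repeats, or paralogy; a clean screen on these
fixtures is evidence about the scanner, not about citrus.

## Problem sizes and numerics

Default test/demo sizes: 12 × 20 kb screening backgrounds, 200-panel and
500-template fuzz loops, 30 kb brute-force-equivalence fixtures — sizes at
which every closed-loop property is exercised in seconds.  Tm values are
reported at 0.1 °C (round-half-up); all tie-breaking in generation and
assignment is lexicographic; coordinates are 0-based half-open internally,
1-based inclusive in human-facing TSV, 0-based half-open in BED.

## Known limitations

No hairpin/secondary-structure screening, no mismatch-specific NN
thermodynamics, no amplification-efficiency or intensity prediction, no
instrument trace parsing.  Scaffold discovery (the original RAPD-derived
basal sequence was found empirically) is out of scope: scaffolds are inputs.
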