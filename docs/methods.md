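# Methods

## The growth model

A nucleus is a sphere of radius *R* centred at the origin; all geometry is
in nanometres. Chromatin is represented at 1 Mbp resolution: one domain =
one bead of radius *r*<sub>b</sub>. A chromosome is a centromere bead plus
a top and a bottom arm, each a chain of beads; homologous pair *p*
contributes chromosomes 2*p*−1 and 2*p*, which are treated identically and
independently (no homology-aware interaction — that is the point of the
null model).

Growth is sequential rejection sampling. Every candidate bead position is
accepted iff it passes all of:

* containment — centre strictly within *R* − *r*<sub>b</sub> of the origin
  (centromeres use the tighter margin *r*<sub>b</sub> + 5ε₂);
* nucleolus exclusion — centre strictly farther than *r* + *r*<sub>b</sub>
  + ε₂ from the nucleolus centre;
* own-chromosome clearance — ≥ 2*r*<sub>b</sub> − 2ε₁ from every bead of
  the same chromosome except the bead it budded from;
* proximity to the own chromosome — nearest own bead within
  *R* − 2*r*<sub>b</sub> − ε₁ (with the default geometry this bound is
  close to the nuclear diameter scale, so it rarely binds; it is kept
  because it is part of the rule set and is cheap);
* foreign-chromosome clearance — ≥ 2*r*<sub>b</sub> + ε₂ from every bead
  of every other chromosome.

All comparisons are strict inequalities; floating-point ties are
measure-zero and resolved by the strict comparison.

The foreign clearance deserves a note. A literal transcription of the
collision inequalities would use 2*r*<sub>b</sub> − 2ε₂ for foreign beads,
which, since ε₂ > ε₁, would let *foreign* beads approach closer than *own*
beads — the opposite of what "territories do not overlap" requires and of
what the accompanying distance diagram shows. The package therefore uses
2*r*<sub>b</sub> + ε₂ (surfaces at least ε₂ apart) by default and keeps
the literal variant behind the `paper_literal` config flag for comparison
runs.

Similarly, two step conventions exist for the distance between a new bead
and the bead it buds from: tangent spheres (2*r*<sub>b</sub>, the default,
matching the stated geometry of consecutive beads) or a half-diameter step
(*r*<sub>b</sub>, `step_mode: literal`, which lets consecutive beads of a
chain interpenetrate). The direction is drawn by the simulator's
spherical-angle convention θ ∈ (0, π), φ ∈ (0, 2π) with
(Δx, Δy, Δz) = step · (cos θ sin φ, sin θ sin φ, cos φ). This convention
is non-standard (the z-component depends on φ) and is *not* uniform on the
sphere — it is implemented as specified because the growth process only
relies on the step length being exact and the azimuth about z being
uniform, both of which hold; the distributional quirk is shared by the
procedure being reproduced, so changing it would change the model.

### Scheduling and precursors

Where the growth order is not dictated by the model, it is fixed for
reproducibility: chromosomes advance round-robin, one bead per turn,
alternating top/bottom arms within each chromosome (condensed phase), and
the same round-robin during decondensation. During condensed growth each
arm extends at its tip; during decondensation the precursory bead of each
new bead is drawn uniformly from the beads of the arm being extended plus
the centromere (the centromere is the root of both arms and the only
possible precursor of an empty arm). `precursor_pool: chromosome` widens
the pool to all beads of unfinished arms of the chromosome, with the new
bead inheriting the precursor's arm. Every bead records its precursor, so
emitted models carry the full growth genealogy and connectivity is
checkable post hoc.

### Failure counting and restarts

A single counter per model attempt counts *consecutive* rejected
candidates and resets on every accepted bead. When it reaches
`restart_after` (default 500 000) the whole attempt — nucleus, nucleolus,
all beads — is discarded and building restarts on the same random stream,
so a fixed (config, seed) reproduces the identical model, restarts
included. `max_restarts` (default unlimited) aborts pathological
configurations. A batch of *n* models reports success rate
*n* / (*n* + total restarts).

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `rad_bead` | bead radius, nm | 250 | a 1 Mbp domain is ~500 nm across; one bead per domain |
| `eps_1` | own-chromosome softening, nm | 0.1·`rad_bead` = 25 | small relative tolerance; lets a chain fold back on itself slightly |
| `eps_2` | foreign/envelope/nucleolus padding, nm | 0.2·`rad_bead` = 50 | must exceed ε₁; keeps territories visually and geometrically disjoint |
| `restart_after` | consecutive failures before restart | 500 000 | large enough that restarts signal genuine dead ends, not bad luck |
| `min_rad_nu`, `max_rad_nu` (set1) | nucleus radius range, nm | 3750–4250 | 7.5–8.5 µm nuclei, typical of root meristem cells; puts the 540-bead *B. distachyon* complement at a chromatin volume fraction of ~13–19 %, dense enough that territories touch but growth completes |
| `min_vol_no`, `max_vol_no` (set1) | nucleolus volume fraction | 0.02–0.06 | a single prominent nucleolus of a few percent of nuclear volume |
| association threshold | border gap defining association, nm | 500 | one bead diameter; the same criterion used on micrographs |

Nuclear and nucleolar dimensions for *B. distachyon* are not published
alongside the karyotype, so the set1 values above are the package's own
calibration, chosen once from cytological plausibility and kept fixed;
they are ordinary config fields for users with measurements.

### Presets

`set1` is the detailed *B. distachyon* karyotype: decondensed totals 75,
59, 60, 48, 28 domains (the Mbp contents), condensed chains 14, 12, 12,
10, 7 beads (metaphase lengths 7.0–3.5 µm at 500 nm per bead; the three
intermediate lengths interpolated linearly in Mbp content, as only the
endpoints are tabulated). Arm splits are assumptions recorded in the
preset file: metacentric Bd1–Bd3 50:50, acrocentric Bd4–Bd5 25:75, one
bead minimum per arm, remainders to the bottom arm. `set2` (23 pairs,
57–249 Mbp) and `set3` (19 pairs, 87–244 Mbp) are benchmark karyotypes
known only as ranges; sizes and condensed lengths are interpolated
uniformly across chromosomes and all pairs treated as metacentric. They
load and validate like any config; at ~7000 and ~6300 beads a single model
is minutes of compute, so the test suite exercises the full pipeline on
`set1` and on toy karyotypes.

## Arrangement classification

The border distance between two bead sets is the minimum over cross pairs
of (centre distance − 2*r*<sub>b</sub>), floored at zero — a surface-gap,
matching the "distance between territory borders" criterion applied to
micrographs. Two arms (or territories) are associated when this gap is
strictly below the threshold.

For a homologous pair the four arm pairings (top:top, bottom:bottom, and
the two cross pairings) yield booleans that map to five classes:
both same-arm pairings → `both_arms`; exactly one same-arm pairing →
`top_top` or `bottom_bottom`; only cross pairings → `top_bottom`; none →
`complete_separation`. Composite patterns are resolved by letting same-arm
evidence dominate cross-arm evidence — a deliberate design choice, since
the class list itself does not enumerate composites —
and `arm_association_profile` exposes the raw booleans so any other
resolution can be computed by the user. Centromere beads belong to neither
arm and do not enter arm-level distances; they do count in whole-territory
(heterologue) distances. Heterologous pairs get a binary
associated/separated verdict on the whole-territory gap.

Classification depends only on pairwise distances, hence is invariant
under rigid motions, and each pair falls in exactly one class (partition).
Frequencies are tabulated per pair over replicate models as counts and
percentages. Pearson's χ² goodness of fit (Σ(O−E)²/E, df = k−1,
upper-tail p) compares an observed class distribution with expected counts
or proportions; expected values are rescaled to the observed total when
the sums differ. The experimental class counts needed to reproduce the
published simulation-vs-FISH comparison are not available in print, so the
package ships the general-purpose test rather than a hard-coded
comparison.

## What the simulations do and do not show

The generator *is* the null model: it realises "fully probabilistic"
territory formation under excluded volume in a spherical nucleus with a
single spherical nucleolus. It does not emulate chromatin loops or
polymer persistence, nucleolus-associated domains, centromere/telomere
tethering (no Rabl configuration), non-spherical nuclei, or chromatin
density differences between chromosomes. Consequently, passing tests show
the *simulator* is self-consistent and that the analysis layer measures
what it claims on known geometry; agreement or disagreement of its
frequencies with real nuclei is a scientific finding about those nuclei,
not a property this package can test.

## Numerical and testing choices

Distance screening is vectorised brute force over the current bead table
(≤ 540 beads for set1); no spatial index is needed at these sizes, and the
post-hoc validator re-checks all O(n²) pairs independently of the growth
path. Model files serialise coordinates with `repr` (shortest
round-tripping decimal), making output byte-stable and read/write an exact
identity; reloaded files are revalidated in full. Test problem sizes: the
replicate-statistics tests use 50 simulated set1 nuclei (~8 s), the
package's standing desk-scale batch; classifier tests run on hand-built
synthetic models with prescribed gaps, so expected classes are known by
construction; the χ² routine is cross-checked against an independent
reference implementation on random tables. Degenerate inputs are defined
behaviour: zero-length condensed arms grow nothing but still decondense
(the centromere seeds the arm), `min_rad_nu = max_rad_nu` gives a fixed
radius, and equal volume fractions give a fixed nucleolus size.

## Known limitations

* `multi` (beads per domain) is validated but only `multi = 1` is
  implemented.
* The centromere-placement margin (5ε₂) is asymmetric with the domain
  margin (0); both are implemented as specified.
* The own-chromosome proximity bound (C4 above) is nearly vacuous with
  the default geometry; chain connectivity, which growth enforces by
  construction, is what actually keeps territories compact.
* Set2/set3 per-chromosome tables are uniform interpolations of published
  ranges, not real karyotypes.
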