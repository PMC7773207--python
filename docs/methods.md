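# Methods

## The problem

*Galesaurus planiceps* is an Early Triassic non-mammaliaform cynodont with
polyphyodont (continuously replacing) teeth. A museum growth series of 17
skulls — basal skull length (BSL) 62–114 mm, spanning juveniles to adults —
shows its maxillary postcanine count rising from 7 to 11–12 through
ontogeny, while the contemporaneous *Thrinaxodon liorhinus* shortens its
row with size. Micro-CT observations of replacement teeth, crypts, root
states and remnant roots in eight of those skulls support a wave
(*Zahnreihe*) organization of postcanine replacement: instead of the usual
every-second-tooth alternation, replacement in *Galesaurus* touches every
third locus (e.g. pc1, pc4, pc7 simultaneously), waves run back to front,
and the canine stops replacing at adult size (~90 mm BSL), its final
generation remaining open-rooted.

This package makes that qualitative model computable: a validated transcription
of the specimen table, the count-trend analysis, a discrete simulator of the
wave model, inference statistics that recover the pattern parameters from
per-locus observations, and a synthetic-data generator that closes the loop.

## Specimen data and normalization

The specimen table stores one row per skull with four per-quadrant counts.
Cells keep the printed conventions: `N?` is an uncertain count (damage can
hide teeth, never add them), `–` an unpreserved or occluded quadrant, and a
`~` prefix an approximate BSL (stored numerically with a flag; arithmetic
uses the numeric value).

BSL is the ontogenetic proxy. For cross-taxon comparison it is min–max
normalized, x' = (BSL − BSL_min)/(BSL_max − BSL_min), over each taxon's own
sample span (62–114 mm here; ~30–96 mm for the comparator). Ontogenetic
stage is classified from BSL as juvenile < 69 mm ≤ subadult < 90 mm ≤ adult.
The subadult/adult boundary is placed at 90 mm because the specimen table
labels the 90-mm skulls adult; this value also matches the canine cessation
threshold. The classification reproduces all 17 printed stage labels.

A specimen's summary count for one jaw is the larger of its two preserved
sides — damage only removes teeth from observation. Trend lines are ordinary
least squares of summary count on (normalized) BSL, via statsmodels; the
figures the analysis mirrors show single straight trend lines, so linear is
the minimal choice, and no hypothesis tests are attached (none are made in
the anatomical argument). Uncertain counts are included at face value by
default, with a strict mode that drops them.

## The replacement-wave simulator

One jaw quadrant is an ordered lattice of postcanine loci (1-based,
mesial→distal), advanced in coarse ontogenetic stages (one lifecycle step
per stage; finer kinetics are unobservable in fossils). The moving parts:

- **Waves.** A wave initiates every `wave_interval_stages` (default 1). Wave
  *w* targets the residue class {ℓ : ℓ ≡ w (mod k)} of lattice ids, with
  `k = wave_spacing_k` (default 3), so k consecutive waves cover every locus
  exactly once. Residues run over absolute lattice ids, which keeps that
  coverage guarantee independent of retirement timing. Within a wave,
  visits spread `within_wave_lag_stages` apart (default 1) in
  `wave_direction` order (default back_to_front: distal-most first). Only
  loci already bearing an erupted tooth are visited — the unerupted distal
  frontier waits for a same-residue wave k waves later.
- **Tooth lifecycle.** A visit opens a replacement episode: the successor
  develops crypt → germ → erupting → functional while the incumbent
  concurrently passes functional → resorbing → shed (its remnant root
  clearing when the successor erupts). These are the two per-locus tracks;
  the only other transition is the absorbing retirement of a locus. A locus
  mid-episode still counts as occupied: the incumbent crown persists until
  its successor erupts, so the functional count is the number of non-retired
  loci that have erupted at least once.
- **Distal addition, mesial loss.** Each wave appends `distal_add_per_wave`
  (default 1) crypts at the distal margin; three stages later they erupt.
  After every `waves_per_cycle` waves (default 3) the mesial-most locus is
  retired — annotated as canine-alveolus invasion, the inferred cause; the
  geometry itself is out of scope — provided it has completed
  `generations_at_mesial_locus` tooth generations (default 2 of the stated
  "two or three"). At steady state this is the +3:−1 triplet: +1 locus per
  wave, −1 per cycle, a net gain of two functional teeth per cycle.
- **Adult slowdown.** Once BSL reaches `adult_onset_bsl_mm` (default 90,
  chosen to coincide with the canine rule; the slowing is placed anywhere in
  80–90 mm by the data) the cycle shortens to `adult_waves_per_cycle`
  (default 2) with unchanged mesial loss — the +2:−1 regime, net +1 per
  cycle. Whether the published +2:−1 means fewer waves per cycle or slower
  within-wave progression is not stated; this implementation chooses the
  former. Overlapping waves need no special casing: with a wave per stage
  several waves are always in the row at once.
- **Canine.** A single locus per quadrant. Below `canine_cessation_bsl_mm`
  (90) it cycles through generations with closed roots (one generation per
  `canine_generation_interval_stages`); at the threshold replacement shuts
  off permanently and the final generation's root opens and stays open. The
  generation count is finite and depends only on the stage at which the
  growth curve crosses the threshold.
- **Incisors.** 4 upper / 3 lower loci replacing in alternating odd/even
  wave groups in antiphase; within a group the distal member is the more
  developed under back-to-front waves, mirrored under front-to-back (the
  data cannot exclude the mirror reading, so both are first-class options).

### Calibration

The published stage diagram's exact schedule is not recoverable from text,
so the default schedule is calibrated to its single stage↔specimen anchor:
stage 8 (the smallest known skull, 62 mm, 7 maxillary postcanines). With an
initial lattice of 4 loci (two functional, a germ and a crypt forming the
growth pipeline), the first wave at stage 2, and the rules above, stage 8
carries exactly 7 functional maxillary postcanines, and a default 13-stage
run (linear BSL map anchored at stage 8 = 62 mm, stage 13 = 114 mm) ends at
10 — inside the printed 7–12 sample range. Stages 1–7 are unobserved in the
fossil record; the early-stage BSL extrapolation is not meaningful and is
never used. The mandibular quadrant runs the same rules from a 6-locus
initial lattice, giving its characteristic two-teeth-longer row (9 at stage
8 against the maxilla's 7).

## Pattern inference

Activity at a locus means replacement evidence: a replacement tooth or a
crypt. Development ordinals are crypt = 1, mineralized germ = 2, and 3 when
the replacement is far enough along that the incumbent root is resorbing;
ties are reported, never broken by guessing.

- **Spacing score.** For candidate period k, the best residue class's share
  of the active loci (max over offsets); 1.0 is perfect periodicity. Loci
  {1, 4, 7} score 1.0 at k = 3 and 2/3 at k = 2.
- **Direction.** An exact Kendall-style concordant-minus-discordant pair
  count between locus index and development ordinal (samples are far too
  small for asymptotics). Positive → back to front; zero (or below a
  configurable floor) → indeterminate.
- **Synchrony.** The fraction of loci, over the union observed on either
  side, whose activity flag matches across left and right.

Quadrants are scored independently and pooled by averaging (direction pair
counts are summed), since the anatomical argument treats quadrants
separately.

## Synthetic data generator

The `galesaurus_like` template runs the simulator once per jaw, samples
specimen stages evenly over the observable range (stage 8 to the final
stage), maps them to BSL linearly with Gaussian measurement noise
(sd 2 mm, clipped to the range), and reads true counts off the trajectory.
Observation tables come from the simulator's clearest in-progress wave at
each specimen's stage. Noise mimics the real table: a quadrant is dropped
("–") with probability 0.2, an uncertain count ("?") with probability 0.15
is reduced by 0 or 1 (equal odds; damage never inflates), and individual
observation rows can be dropped. The published table gives no quantitative
missingness rates; these defaults loosely match its frequencies of "–" and
"?" and are configuration, not claims.

The `thrinaxodon_like` comparator is rule-based rather than a second full
simulator parameterization: maxillary count 7 below 56 mm BSL and 6 above,
mandibular 8 then 7–8 at random — the published juvenile-to-adult decline
and adult stabilization (6–7 maxillary / 7–8 mandibular; the deterministic
6 keeps the declining-trend contrast sharp while staying inside the printed
adult range). Its observations alternate every second locus (spacing 2),
most developed distally.

What the generator does **not** emulate: real μCT ambiguity (partially
mineralized germs, segmentation error), taphonomic geometry, left/right
developmental asynchrony beyond an optional phase offset, and inter-individual
variation in wave timing. Passing recovery tests therefore shows the
inference statistics are consistent estimators of the model's own pattern,
not that the fossil record uniquely identifies it.

## Numerical choices

- Percent size ratios round half-up to integers (88/114 → 77%, 87/96 → 91%).
- The trend fit is exact OLS; collinear points are recovered to 1e-9.
- The simulator is fully deterministic; the generator derives all noise from
  a single seeded NumPy generator, so a fixed seed reproduces output
  byte-for-byte.
- Degenerate inputs raise: zero-span normalization ranges, counts in the
  wrong order for the wave arithmetic, non-monotone stage→BSL maps,
  all-true/all-false canine evidence, fewer than two usable trend points.
- Problem sizes in the test and acceptance runs — 13–25-stage simulations,
  1,000 randomized property runs, 20 recovery replicates — are desk-scale
  by design; everything completes in seconds.

## Known limitations

- Lattice ids are positions, not homology claims: the mesial-most tooth of
  a small skull need not be homologous with that of a large one (the source
  material doubts it explicitly).
- The +2:−1 adult regime and the 90-mm onset are interpretations of a
  pattern the data only brackets (80–90 mm).
- The incisor direction reading is structurally ambiguous; the inference
  layer reports the gradient and its sign rather than a hard claim.
- Trend lines are descriptive; no uncertainty is attached to slopes.
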