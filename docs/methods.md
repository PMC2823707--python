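# Methods

## The multi-state hybridization model

A surface-tethered DNA probe reaches its bound state only from fully
accessible reactants. The model therefore treats hybridization as a
competition between four states — the probe-target duplex, the folded
probe, the folded binding site in the target, and probe-probe dimers inside
the same array feature — and scores a probe by the effective interaction
energy

    dG = dG_h − dG_p − dG_t − dG_pp,

with all of dG_h, dG_p, dG_t, dG_pp ≤ 0 (an unstable competitor contributes
exactly zero; clamping is applied per term, and dG itself is reported
unclamped). dG ≥ dG_h is an algebraic consequence and is asserted for every
emitted profile.

Component definitions:

* **dG_h** — nearest-neighbor free energy of the probe against its exact
  complement. Perfect-match duplexes only; mismatch, dangling-end and
  coaxial-stacking corrections are out of scope. DNA targets use the
  unified DNA/DNA parameters; RNA targets use the orientation-specific
  RNA/DNA hybrid set (keyed by the RNA strand 5'→3'). A contiguous perfect
  helix is used rather than an interaction ensemble over partial pairings;
  this is the documented default for the duplex term.
* **dG_p** — sign-flipped ensemble free energy (−RT ln Z) of the whole
  probe, not merely its binding region: the entire probe must unfold to
  hybridize. Probes always fold with DNA parameters.
* **dG_t** — sign-flipped opening energy of the binding site inside a
  target fragment that extends up to 200 bases on each side of the site
  (intramolecular contacts rarely reach farther). The opening energy is
  −RT ln P(site fully unpaired) = RT(ln Z − ln Z_constrained), computed as
  the single contiguous binding-site constraint; averaging over partial
  interaction sites is deliberately not attempted. RNA targets fold with
  RNA parameters, cDNA targets with DNA parameters.
* **dG_pp** — ensemble free energy of intermolecular-only pairings between
  two probe copies (both otherwise unstructured), with consecutive pairs
  separated by at most 30 unpaired bases, clamped at ≤ 0 and exactly 0
  when no Watson-Crick contact exists. No translational-entropy/strand-
  concentration term is applied: dG_pp is a per-probe quantity.

The optional poly-T linker of in-situ synthesized probes is metadata only
and excluded from every thermodynamic computation.

## Melting temperature

    Tm = 1000·dH / (dS + A + R·ln(Ct/4)) − 273.15
         + 16.6·log10([Na+]) − 0.63·F

with dH in kcal/mol, dS in cal/(K·mol), the helix-initiation factor
A = −10.8 cal/(K·mol), R = 1.987 cal/(K·mol), total strand concentration
Ct = 6.1e−17 M, [Na+] = 0.6 M and F the formamide percentage. Defaults
reproduce the hybridization buffer of the modelled NimbleGen protocols; the
profile pipeline leaves F at 0 unless the caller sets it. Design choices:

* the `Ct/4` convention assumes non-self-complementary strands; the divisor
  is a configurable field (`ct_divisor`) for the self-complementary case;
* the 16.6·log10[Na+] salt term is the classical variant; it applies to Tm
  only, never to folding free energies;
* both corrections carry independent on/off switches so sensitivity runs
  can reproduce the uncorrected limit exactly;
* Tm is always computed from the DNA/DNA parameters (the standard method
  for array probes), even when dG_h uses the hybrid table — Tm is a
  predictor in its own right, not a component of dG;
* the DNA/DNA table ships with zero duplex initiation because initiation
  enters through A; the RNA/RNA and RNA/DNA tables keep their published
  initiation terms, which matter for short duplex ensembles.

## Secondary-structure engine

Pseudoknot-free loop decomposition over Watson-Crick pairs: stack energies
dH − T·dS/1000 from the nearest-neighbor tables (the closing pair of a
stack determines the table key because pairing is WC-only), length-dependent
hairpin (≥ 3 unpaired), bulge and internal-loop penalties, and a linear
multiloop model a + b·branches + c·unpaired. Wobble pairs are excluded —
the named duplex parameter sets provide no wobble stacks — and there is no
lonely-pair prohibition. Numerical/convention choices:

* interior loops are capped at 30 unpaired bases total (field standard);
  the exhaustive enumerator applies the same cap so oracle comparisons are
  exact;
* loop penalties ship as dG at 37 °C with anchor sizes filled in by
  Jacobson-Stockmayer extrapolation (1.75·R·T·ln(n/anchor)) and are treated
  as purely entropic: dG(T) = dG37 · T/310.15 — the sources provide no
  enthalpy split, and loop costs are entropy-dominated;
* the folding temperature defaults to 37 °C (native temperature of the
  parameter sets) and is configurable everywhere;
* coordinates are 0-based half-open; sequences are stored 5'→3';
* partition functions are computed in plain float64 — Z stays far below
  overflow for the strand lengths this package targets (≤ ~1 kb);
* constrained folds reuse the unconstrained matrices for every interval
  that does not intersect the blocked region, roughly halving the cost of
  per-site accessibility scans; mfe traceback compares loop contributions
  at 1e−6 kcal/mol tolerance and falls back to "unpaired" on a failed
  match, so a tie can never abort a traceback;
* the enumerator (`enumerate_structures`) refuses strands longer than 20 nt
  and is the independent oracle for the partition function, mfe, opening
  and dimer programs on short random sequences.

The packaged stack tables are the published unified DNA/DNA, RNA/RNA and
RNA/DNA hybrid nearest-neighbor sets. The loop tables are standard-magnitude
penalties at anchor sizes; their absolute values matter less here than
self-consistency, since every structure-dependent quantity in the package
(and every oracle check) derives from the same tables.

## GUIDE-style importance ranking

At each tree node a least-squares linear model on all predictors is fitted;
its residual signs feed unbiased chi-square selection tests: curvature
(signs × quartile bins of one predictor, 2×4 table) and interaction (signs
× the four cells of the median-half grid of a predictor pair). The winning
test (smallest p-value; ties resolve toward column order, an interaction
win resolves to the member with the stronger curvature) chooses the split
variable; the split point minimizes the summed children SSE of the
piecewise-constant model by exhaustive search (ties toward the smaller
threshold). Growth stops at `min_node_size` (default 50) or `max_depth`.
Cost-complexity pruning with k-fold CV (default 10) selects the smallest
tree within one standard error of the minimal CV error; the pruning trace
(candidate alphas, CV errors, SEs, chosen alpha) is retained on the tree.

Importance of a predictor is Σ over split nodes of the selection-test
chi-square × √(node size). By default only the winning variable accrues
score at a node; the `losing_vars_score` switch credits every variable its
own curvature statistic instead, since the attribution convention for
losing variables is genuinely ambiguous. Bootstrap replication (resampling
with replacement at a fixed size, or 90% subsampling) yields means, SDs and
relative scores scaled by the top predictor's mean; replicate streams are
spawned from a single seed, so results are bit-reproducible.
`bootstrap_importance` grows unpruned trees by default: pruning controls
prediction overfit, while the deep noise nodes it would remove carry
near-zero chi-square weight in the importance sum (a unit test checks that
the top-ranked predictor is unchanged by pruning).

Spearman correlations use average ranks; p-values come from the
t-approximation for n > 8 and from the exact permutation distribution
otherwise. Constant vectors raise an undefined-correlation error, which the
CLI maps to NaN for degenerate predictors such as a fixed probe length.

## Synthetic data

`synth` generates i.i.d. random targets at a configurable GC content,
reverse-complement tiling probes, and intensities. Two presets mirror the
modelled experimental regimes: `cdna` (45–75-mers at 22 nt resolution on
DNA targets, half the targets expressed) and `rrna` (fixed 25-mers at 1 nt
resolution on nine RNA targets, every target expressed — each rRNA is
hybridized to its own array compartment).

Signal model: occupancy follows a Langmuir isotherm θ = K/(1+K) with

    ln K = −(dG − dG_ref) / (m · R · T),

dG_ref defaulting to the median dG of the probe set (a pseudo-concentration
reference) and m a heterogeneity/compression exponent. A strict two-state
isotherm (m = 1) saturates numerically — exp(46/RT) overflows θ to exactly
1.0 in float64 at typical effective energies — whereas surface
hybridization is well documented to show a compressed apparent dependence
on solution free energies; m models that compression and keeps intensity
strictly decreasing in dG. Fluorescence is
scale·θ·exp(σ·ε) + background·exp(σ_b·ε'): multiplicative lognormal probe
noise plus lognormal optical background; non-expressed targets receive
background only. The defaults m = 14 and σ = 0.30 were calibrated once so
that the cdna preset's per-target mean log2(max/min) intensity ratio lands
near 4.2 (about 18-fold), the regime typical of expressed transcripts on
tiling arrays; the acceptance script recomputes this statistic (≈ 4.2 at
the default seed). Signals can alternatively be driven by Tm
(`driver="Tm"`, scaled at 4 °C per ln K unit) to emulate the non-specific
regime in which melting temperature, not the effective energy, explains
probe behaviour.

What the generator does **not** emulate: cross-hybridization to near-match
non-targets, target-target interactions, target fragmentation and labelling
chemistry, spatial array artifacts, and realistic transcript base
composition (targets are i.i.d.). Passing recovery tests therefore shows
that the pipeline identifies the generating energy term under the model's
own assumptions — not that real arrays obey the Langmuir form.

## Benchmark problem sizes

The test suite runs the oracle comparison on 200 random 8–14 nt sequences
per folding chemistry (plus 200 duplex pairs per duplex chemistry), the
model-identity checks on ≈ 10,400 profiled 25-mers tiling 78 RNA targets,
the predictor-recovery benchmark on ≈ 5,300 long probes tiling 660 cDNA
targets of 150–300 nt (100 bootstrap replicates of 90% subsamples), and the
steric simulation on ≈ 2,100 fixed-length 60-mers tiling 300 targets. The
acceptance script uses the same designs at roughly half these sizes. These
scales give stable rankings and tight oracle bounds while keeping a full
run in the minutes range on a single CPU.

In the steric simulation the signal is generated from the effective energy
of the probe minus its five tethered-end bases (those bases carry no
weight, emulating surface crowding). Associations are compared as Spearman
correlations; the solution-end truncation is tested for significant
degradation against full length with Steiger's z for dependent correlations
(one-sided p < 0.01), while the tethered-end truncation is required not to
degrade the association (it may sharpen it, since the inert bases only add
noise to the full-length energy).

## Known limitations

* The duplex term is a perfect contiguous helix; partial-pairing
  interaction ensembles (RNAup-style joint probe-target partition
  functions) are out of scope, as is any pseudoknot.
* Folding uses Watson-Crick pairs only; G·T/G·U wobbles are absent, which
  slightly understates structure stability, consistently across all terms.
* dG_t conditions on one contiguous site; partial site accessibility is not
  averaged over sub-sites.
* The GUIDE realization implements numeric predictors, the published
  curvature/interaction selection tests and CCP pruning, but none of the
  original program's categorical handling, missing-value logic or
  kernel/nearest-neighbor leaves; exact score reproduction of the original
  binary is not a goal.
* Salt/formamide corrections apply to Tm only; folding energies are at the
  parameter sets' native 1 M NaCl reference conditions.
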