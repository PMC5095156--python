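# Methods

## Scope and model

kerassign interprets residue-type-resolved ¹³C spectra of uniformly
labelled keratin. It deliberately models none of the pulse-sequence physics
(cross-polarization dynamics, DQ excitation efficiency, spin-diffusion rate
matrices): the unit of modelling is the *peak list*, and the physical
content is carried by three rules.

1. **DQ sum rule.** A bonded ¹³C pair (i, j) produces DQ–SQ cross peaks at
   (F2, F1) = (δᵢ, δᵢ+δⱼ) and (δⱼ, δᵢ+δⱼ). When |δᵢ−δⱼ| is below an
   *equivalence window* (default 2.0 ppm, the scale of the Phe ring
   envelope) the pair collapses to one autocorrelation peak at
   ((δᵢ+δⱼ)/2, δᵢ+δⱼ). Under a collapsed peak the two shifts are not
   separable; consumers of consensus shifts should expect envelope
   positions for such atoms.
2. **PDSD proximity rule.** Cross peaks appear for every atom pair within k
   bonds of each other, where k is a stepwise function of mixing time
   (≤20 ms → 1, ≤100 ms → 2, >100 ms → 3). The breakpoints encode the
   empirical observation that short mixing resolves one-bond aromatic
   proximities while ~100 ms reveals two-bond pairs such as Cδ–Cζ; they are
   configurable and make no claim to quantitative transfer rates.
3. **Index rule.** Helix and sheet/coil environments shift Cα and Cβ in
   opposite directions, so δCα−δCβ is a secondary-structure indicator that
   is exactly invariant to the referencing convention. A residue is
   classified to the structure class whose reference index (reference Cα −
   reference Cβ per class) is nearest; exact ties resolve helix > sheet >
   coil and are flagged. Gly has no Cβ and is never classified.

## Bond graphs

The 20 standard amino acid carbon skeletons are packaged as tabular data.
Aromatic near-equivalent positions (Phe/Tyr Cδ1/Cδ2, Cε1/Cε2) are collapsed
to single representatives by default — matching the one-shift-per-position
reporting convention of residue-type-resolved data — with an expanded mode
that restores the six-membered ring; collapsing the ring to the path
Cγ–Cδ–Cε–Cζ preserves all inter-position bond distances. Carbons bonded
only through heteroatoms (Arg Cζ, Met Cε, His Cε1) are isolated nodes: they
yield no DQ–SQ peak but appear in 1D spectra and on the PDSD diagonal. The
graph-connectivity invariant therefore applies to the bonded subgraph only.

## Reference shifts (two tables)

- `observed_shifts_fur.csv`: the observed fur-keratin assignments, with
  per-entry provenance. Where the running text and the printed table
  disagree (Tyr Cζ 155 vs 156 ppm; Phe Cγ 137 vs 140 ppm) both values are
  retained under distinct provenance tags rather than reconciled. Rows not
  typeset as high-certainty, the Arg/Lys spin systems (not uniquely
  resolved) and the Ala Cβ (tentative) carry a `tentative` flag.
- `reference_shifts.csv`: per-class (H/S/C) Cα/Cβ values assembled from
  published random-coil shifts plus consensus average secondary shifts
  (helix ΔCα +2.6 / ΔCβ −0.4; sheet ΔCα −1.4 / ΔCβ +2.2 ppm). Proline uses
  structure-specific statistical means, since uniform offsets are known to
  be inapplicable to it. C=O entries implement the two-component amide
  model (175 ppm helix, 172.5 ppm sheet/coil); side chains are
  class-independent (observed fur values where available, typical protein
  values otherwise). The file is plain text and swappable: classification
  quality is bounded by the reference choice, and agreement for tentative
  rows genuinely depends on it.

## Matching and assignment

Peak matching is optimal one-to-one assignment (Hungarian algorithm on the
bipartite squared-distance graph) with pairings forbidden beyond a per-axis
tolerance; the score is the total squared ppm distance. The default SQ
tolerance is 0.5 ppm, a typical moderate-field linewidth. On the DQ axis
the coordinate is a *sum* of two shifts, so its deviations are larger (the
noise of two atoms adds, and DQ linewidths are roughly double); the
assignment pipeline therefore admits F1 deviations up to twice the SQ
tolerance. Ties in processing order are broken deterministically (lower F2,
then lower F1; residues by descending mole %, then alphabetically).

For each residue type all three structure-class reference hypotheses are
matched and the one with the most matched peaks (lowest score on ties)
wins. Matching is non-exclusive across residues: overlapped spectra
genuinely superimpose, and the observed assignment practice reports the
same backbone positions for Tyr and Phe. The abundance prior instead
governs reporting — a matched peak that also lies within tolerance of
another residue's winning prediction counts as ambiguous, and a residue is
`resolved` only if at least one unambiguous matched peak remains.
Consensus shifts use the DQ sum rule in both directions: a matched cross
peak contributes its F2 to the F2-side atom and F1−F2 to the partner, the
same way partner shifts are read off the DQ coordinate manually. This makes
the recovered index robust to losing one side of a pair.

Assignment tables are ordered by descending mole %. Residues with no
matches, or below the abundance floor (default 2.0 mole %, the His/Met
scale), are flagged `unobserved`; grouped hydrolysis entries (Glu/Gln,
Asp/Asn) are merged and never better than `tentative`.

## Amide decomposition

The 165–185 ppm region is fitted with two Gaussians (pseudo-Voigt behind a
flag) plus an optionally co-fitted linear baseline, by bounded
least-squares with a deterministic start. Initial centers default to 172.5
and 175 ppm and are bounded within ±2 ppm to prevent the components from
swapping roles; components are reported in ascending center order with
area fractions (amplitude × FWHM, normalized). Negative amplitudes are
clamped to zero and flagged. Fractions are invariant to intensity scaling,
and centers are covariant with a global ppm offset.

## Synthetic data: what it emulates, what it does not

Each replicate draws, per residue type, one structure class from a class
mix (default 40% helix, 30% sheet, 30% coil — helical rod domains dominant
with substantial sheet/coil head, tail and matrix content), takes the
per-class reference shifts, and adds i.i.d. Gaussian noise (default sd 0.2
ppm). Intensities are mole % × labelling efficiency (default 1.0 for
essential amino acids, 0.6 for non-essential — an assumed value
operationalizing the unquantified observation that de novo biosynthesis
dilutes non-essential labelling), with correlations involving
non-protonated aromatic carbons attenuated (default ×0.2). An optional
lipid pseudo-residue contributes the 30 ppm methylene autocorrelation.
Rasterization sums 2D Gaussians (default FWHM 0.5 ppm, ~50 Hz at 100 MHz
¹³C — chosen at the narrow end of plausible linewidths so that rasterized
peaks remain separable at the matching tolerance; the generator makes no
claim to lineshape fidelity) on a 0.1 ppm grid, and picking takes local
maxima with 3-point parabolic sub-pixel refinement.

The generator assumes one shift per residue type per replicate (no
site-to-site heterogeneity within a type), symmetric Gaussian lines (no CP
dynamics, relaxation, spinning sidebands or t1 noise), and class-independent
side-chain shifts. Passing recovery tests therefore demonstrates the
correctness of the interpretation chain under the stated statistical
conditions, not performance on real spectra, where within-type
heterogeneity and baseline artifacts will lower effective resolution.

A residue is treated as *index-resolvable* in recovery tests when its Cα
and Cβ each contribute at least one predicted peak overlapping no other
residue type's predictions — mirroring the practice of classifying only
residues whose Cα/Cβ signals are resolvable. Under the default conditions
(18 residue types, 0.2 ppm noise, 0.5 ppm linewidth, 0.1 ppm grid) the full
generate→render→pick→assign→classify chain recovers the generating class
for all index-resolvable residues in ≥90% of 50 seeded replicates.

## Numerical choices and problem sizes

All randomness flows through explicit integer seeds (numpy Generator); the
same config and seed reproduce peak lists bitwise. Test and acceptance
problem sizes — 50 assignment replicates, 100 amide-fit replicates on a
0.05 ppm grid, rasters at 0.1–0.2 ppm/pt — run in seconds to a couple of
minutes on one CPU and were chosen as the smallest sizes at which the
stochastic checks are stable.

## Known limitations

- Residue-type resolution only: no sequential or site-specific assignment.
- Classification collapses structure to three classes on a scalar index;
  populations within one residue type (e.g. part-helix, part-coil Ser) are
  invisible except through the amide decomposition.
- The Lys and Ile printed class calls are not reproduced by the packaged
  reference table (both tentative rows); agreement there depends on which
  published reference variant is used, and is reported rather than
  guaranteed.
- Cystine chemistry (disulfide-specific Cβ shifts) and post-translational
  modifications are not modelled.
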