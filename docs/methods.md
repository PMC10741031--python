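# Methods

## Mass arithmetic

Monoisotopic masses use most-abundant-isotope IUPAC atomic masses to
≥ 6 d.p. (C 12 exactly, H 1.00782503, O 15.99491462, N 14.00307400,
S 31.97207100), hard-coded in `chem_mass.ATOMIC_MASS`.  The theoretical
*m/z* of an anion is the plain monoisotopic mass of the tabulated ion
formula divided by the charge magnitude, with **no electron-mass
correction**: this convention reproduces the packaged ion table's printed
ppm errors (gallic acid 4.7 ppm), which the electron-corrected convention
(−3.2 ppm at *m/z* 169) does not.  Display rounding is 4 d.p. for *m/z*
and 1 d.p. for ppm, matching the table.

Ion species are defined by (multimer count *n*, charge *z*, signed atom
delta): [M−H]⁻, [2M−H]⁻, [M−2H]²⁻ and [M+HCOOH−H]⁻ cover everything in
the library.  Species conversion goes through the neutral mass —
``M = (mz·z − Δ)/n`` — and round-trips to 1 × 10⁻⁹.

The homolog catalog defaults to methylation +14.0157, dehydration
−18.0106, decarboxylation −43.9898, ketene −42.0106, galloyl residue
+152.0110, gallic acid +170.0215 and hexose residue +162.0528 Da, each
capped at multiplicity 5 and extendable via JSON.  The 164/156 Da
differences seen in some networked chebulanin derivatives are left as
unannotated differences in the homolog catalog (their chemistry is not
established); a hexitol-residue loss (164.0685) appears only in the
diagnostic-rule loss set, where it explains the galloyl-hexitol fragment
arithmetic.

## The compound library

122 records transcribed verbatim from the reference ion table, including
its quirks: two distinct entries named MN-18 (records 9 and 84, kept under
distinct ids), em-dash CCS cells stored as null, and fragment values at
whatever precision was printed.  Three corrections/annotations, applied
only where the table contradicts itself:

* records 36 and 43 print an ion formula (C34H23O23) inconsistent with
  their own printed mass and ppm error; the fixture stores C34H23O22,
  which reproduces both (and is the deprotonated form of terflavin B's
  known composition);
* records 8 and 96 print ppm errors that contradict their own printed
  formula + observed mass by ~1 and ~3 ppm; the printed values are kept
  verbatim and the ids are exposed as
  `compound_library.INCONSISTENT_PPM_RECORDS`, excluded from
  ppm-recomputation consistency checks (which otherwise hold to 0.2 ppm,
  the rounding slack of 4-d.p. observed masses);
* record 90 prints two predicted CCS values for its two candidate
  structures; the first is stored.

The canonical serialization is JSON (fragment lists are ragged); a flat
CSV round-trip with semicolon-joined fragments is provided.

## Molecular networking

Modified cosine: intensities are square-root transformed and L2-normalized
per spectrum; peaks are pairable directly (|Δm/z| ≤ tol) or shifted by the
precursor mass difference; the one-to-one pairing maximizing the summed
intensity products is solved **exactly** as a linear assignment
(`scipy.optimize.linear_sum_assignment`) rather than by the common greedy
heuristic.  Exact ≥ greedy everywhere, and the score equals the
brute-force enumeration oracle on toy spectra; the greedy reference
implementation (matchms) is used in tests as an independent cross-check,
never as the implementation.

Network construction follows the classic-networking conventions: all
pairs scored; edges kept at cosine ≥ 0.7 with ≥ 6 matched peaks; each edge
must rank in both endpoints' top-10; components above 100 nodes are pruned
by weakest-edge removal; degree-0 nodes are flagged orphans and excluded
from component numbering.  The 0.01 Da fragment/precursor tolerances are
the source analysis's stated settings; the remaining defaults are the
standard public-workflow defaults, stated here as this package's choices
and all exposed via `NetworkParams`.  Component classes are labelled by
majority (≥ 50%) vote of annotated nodes; unannotated members inherit the
label as a propagated, not asserted, class.

## Diagnostic classification

Classification is a prioritized rule cascade over fragment ions and
neutral losses with a 0.01 Da tolerance, priority chebuloyl > HHDP >
galloyl (the classes nest: chebulagic acid shows both 337.0201 and
300.9990 and is a chebulic ellagitannin).  Beyond the four canonical
markers, the default catalog encodes fragment families learned from the
standard constituents' cleavage behaviour — methyl/dimethyl-chebulate ions
(351.0345/365.0502), chebulanin-family ions (203.0344/337.0560/409.0770),
the chebulanin-derivative ion 435.0556, chebulate ester companions
(205.0506/193.0141/249.0401/231.0290, required in pairs and only at
precursor ≥ 450 Da to separate glycosylated chebulates from free
chebulic-acid derivatives), dehydro-ellagic ions (298.9832/270.9880),
the shikimate marker 93.0344, glucose cross-ring ions
(313.0565/271.0459/211.0243) and the gallate-ester radical ion 124.0166.
The phenolcarboxylic-acid vs gallotannin boundary (precursor < 550 Da, no
glycosyl-loss evidence) is a documented heuristic.  All rules are plain
data (`DiagnosticRule`), serializable to JSON.

On the library's own 106 phenolcarboxylic/tannic fragment lists the
cascade recovers the tabulated class for 94% of records.  The six
mismatches are intrinsic: ellagic acid, terminalin and flavogallonic acid
carry the HHDP/dehydro-ellagic markers themselves (classified
ellagitannin, tabulated phenolcarboxylic), digallic acid shows a genuine
galloyl loss (classified gallotannin), and two networked compounds lack
any family ion of their tabulated class in their printed list.  Accuracy
is reported, not forced: the acceptance bar is ≥ 80% with chebuloyl
soundness — no chebulic-ellagitannin call without a chebuloyl-family
ion — at 100%.

CCS comparison: relative deviation |measured − predicted|/predicted × 100,
matched at ≤ 3% by default.  A flagged comparison demotes the affected
candidate but never deletes it, because CCS prediction is reliable only
for the small galloyl glucoses and degrades for large tannins.

Evidence integration is a fixed precedence: standard-confirmed library
hit > library hit consistent with the diagnostic class > diagnostic class
(homolog-supported or not) > homolog lineage > network-propagated class;
conflicting streams keep the higher-precedence class and set a conflict
flag; candidates are de-duplicated by record id.

## Chemometrics

Pre-treatment is unit-variance autoscaling (constant peaks dropped with a
warning) — the usual default of commercial multivariate software; the
choice is this package's, as the source workflow does not state its
scaling.  Fingerprint similarity is the cosine (congruence) coefficient
against the mean fingerprint by default (median or a named batch are
options).  HCA defaults to Ward linkage on Euclidean distance of
autoscaled areas with scipy's deterministic tie-breaking; PCA is SVD-based
with a deterministic sign convention (largest-magnitude loading positive).

OPLS-DA (two classes, ±1-encoded and centered) removes `n_orthogonal`
orthogonal-signal components before one predictive PLS component.  R²X is
the fitted X-variance fraction across all components, R²Y the fitted
y-variance fraction; Q² uses k-fold cross-validation (default 7 folds,
contiguous blocks in batch order, refitting centering per fold).  VIP uses
the SSY-weighted squared loading weights over all components, so
ΣVIP² = p exactly; orthogonal components carry zero SSY and therefore do
not dilute the identity.  With 0 orthogonal components the model equals
single-component PLS-DA (verified against scikit-learn's PLSRegression).

## Spectrum–effect correlation

IC₅₀ is log-linear interpolation at the first 50% crossing —
assumption-light and exactly testable; four-parameter logistic fitting is
left as an extension point.  Pearson flags use the study's thresholds
(r < −0.5 vs DPPH IC₅₀, r > +0.5 vs both T-AOC assays).  Grey relational
analysis is Deng's form with resolution coefficient ρ = 0.5, min-max
normalization by default (mean normalization available — the variant
choice changes the degrees and is therefore exposed), global Δmin/Δmax,
and a 0.7 degree cutoff.  The reference sequence defaults to 1/IC₅₀ so
that "better antioxidant" is monotone-increasing, matching the sign
convention of the T-AOC references.  DPPH decrease is the mean percent
area decrease across replicates (n = 6 by default); no hypothesis test is
applied since raw percents are the reported quantity.  The consensus ranks
peaks by method votes (dual Pearson flags, GRA ≥ cutoff, DPPH decrease
positive and above the 75th percentile), ties broken by DPPH decrease.

## Synthetic design

The default design mirrors the study layout: 18 batches (groups of 5/7/6;
groups I–II emulate whole fruits, group III flesh) over the 23 common
constituents.  Group mean areas plant the reported structure — chebulagic
acid dominant in group I, chebulinic acid in group II, ellagic and gallic
acid elevated and every tannin depressed in group III — with the I-vs-II
contrast of the two dominant tannins set large enough (≈ 2.7-fold) that
the three groups separate in HCA/PCA as cleanly as the published
clustering, at the default 15% log-normal area CV.  Eight peaks are
planted as group-discriminating markers and six as antioxidants
(activity = weighted sum of their areas; IC₅₀ inversely proportional,
scaled so fruit batches land near 3.0–5.3 µg/mL and flesh batches near
5.8–10.1 µg/mL).  Per-peak DPPH susceptibility defaults to 22–43% for the
planted antioxidants (the top value reproducing the 43.16% benchmark
decrease) and 3% otherwise.

Spectra are synthesized from the library's printed fragment lists with a
geometric intensity decay over the printed order (the lists are assumed
prominence-ordered; the truth map keeps tests independent of this
assumption), Gaussian fragment jitter in Da (default 0.002, well inside
the 0.01 Da matching tolerance) and precursor jitter in ppm (default 3,
well inside the 10 ppm search tolerance) so search behaviour is uniform
across the mass range.  Exact duplicate fragment values (one record prints
a fragment twice) are merged.

**What recovery means here.**  In the correlated study-like design, the
activity pattern coincides with the group pattern, so any tannin-patterned
peak genuinely correlates with activity — an exact-set read-out of
Pearson flags or VIP selection is ill-posed by construction, exactly as in
the real data (where a peak could be correlation-flagged yet fall below
the VIP threshold).  Recovery is therefore defined as: the planted
antioxidants top the three-method consensus (exact top-6 set); and, for
VIP, the planted markers occupy the top 8 ranks with VIP > 1 in an
orthogonal variant of the design (`flat_baseline=True`, only the markers
patterned) where exact identifiability holds.  Classification/annotation
recovery counts a spectrum as mapped when its source record is among the
ranked candidates, since co-eluting positional isomers (six
tri-galloylglucoses within 2 ppm of each other) are genuinely
indistinguishable by precursor and fragment list alone — discriminating
them is what the CCS comparison is for.

**What the generators do not emulate:** chromatographic drift and peak
overlap, isotope envelopes, in-source fragmentation, matrix effects on
the assays, and between-assay disagreement.  Passing recovery tests shows
the pipeline recovers planted structure under log-normal area noise and
Gaussian m/z jitter; it does not certify performance on real instrument
data.

## Known limitations

* The published molecular network and the multivariate statistics of the
  real fingerprints are not reproducible without the undeposited raw
  data; they are emulated, with recovery properties standing in for the
  printed figures.
* The classifier is tuned to the phenolcarboxylic/tannic chemistry of
  this matrix; flavonoids and triterpenoids are deliberately left
  unclassified rather than guessed.
* Acylation-site (regiochemical) assignment is out of scope; CCS
  comparison can demote implausible isomer candidates but cannot place
  galloyl groups.
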