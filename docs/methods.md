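# Methods

## Scope and model structure

`odorsafe` estimates, from structure alone plus a vapor pressure, the
maximum concentration of a volatile chemical in solution such that inhaling
one equilibrium headspace volume per day cannot exceed a hazard-based
Threshold of Toxicological Concern (TTC). It is a screening model for
data-poor chemicals — typically novel odorants evaluated by brief sniffing —
not a substitute for chemical-specific toxicity data.

The pipeline has two parallel branches joined at the end:

* a **toxicology branch**: structural-alert mutagenicity screening, Cramer
  decision-tree classification, severity precedence
  (mutagen > Cramer III > II > I), and TTC lookup;
* a **physical-chemistry branch**: ideal-gas headspace mass from the vapor
  pressure, with Raoult mole-fraction scaling for solutions.

Dividing the TTC by the neat-solution daily exposure, capped at 100 %,
yields the recommended maximum concentration.

## Hazard rulebooks

All three rulebooks are versioned CSV files shipped inside the package;
their SHA-256 checksums are logged at load time and stamped into every
result's audit trail and output-file metadata.

**Mutagenicity.** Thirty SMARTS alerts encoding the ISS / Benigni–Bossa
in vitro (Ames) mutagenicity alert list (SA1–SA30; alerts relevant only to
the in vivo/carcinogenicity branches of that rule base are deliberately
absent). Only the binary outcome — any alert vs none — feeds TTC
assignment, so the encoding degrades conservatively: a missed alert can
only make a prediction less strict, never stricter. Known coarse spots:
SA11 fires on all simple aldehydes (including benzaldehyde) and SA28 on all
primary aromatic amines; both mirror the deliberately sensitive character
of the parent rule base.

**Cramer tree.** A condensed, data-driven encoding of the published Cramer
question sequence: each CSV row is one yes/no question (structural
predicate → successor question or terminal class), and the classifier
returns the exact traversal path for audit. Question ids follow the
published numbering where the question is retained (Q1, Q2, Q3, Q5, Q6,
Q7, Q8, Q19); QA-suffixed ids mark condensation points. The encoding
covers the volatile-odorant space the package targets:

* acyclic hydrocarbons and common carbohydrates → Class I;
* open-chain/alicyclic structures bearing only readily metabolized C/H/O(/divalent S)
  functional groups (alcohol, ether, carbonyl, acid, ester, alkene, thiol,
  sulfide) → Class I; any nitrogen or other unusual feature → Class III;
* mononuclear benzene derivatives with the same innocuous substituent set
  → Class I; fused or substituted otherwise → Class III;
* heteroaromatics → Class III;
* saturated oxygen heterocycles with innocuous substituents (terpenoid
  ethers, simple saturated lactones) → Class II; α,β-unsaturated or
  aromatic-fused lactones and other heterocycles → Class III;
* the "enhanced toxicity" gate (secondary aliphatic amine, cyano,
  N-nitroso, diazo/triazeno, quaternary nitrogen) and the unusual-element
  gate (anything outside C/H/O/N/divalent-S) → Class III.

This is intentionally not a bug-compatible reimplementation of Toxtree's
revised Cramer tree, whose extensions exist only in its source; structures
outside the encoded space (complex natural products, polyfunctional
molecules) may diverge, usually toward the conservative Class III. Users
who run Toxtree directly can supply its verdicts as per-chemical overrides
(`--overrides`), which replace the structure-based classification while the
cohort-of-concern screen still runs. Molecules containing elements outside
H/C/N/O/P/S/halogens (organometallics, silicones) raise an out-of-domain
error rather than receiving a silent class.

**Cohort of concern.** Five exclusion classes for which TTC screening is
invalid — organophosphates, dibenzodioxins, alkyl azoxy compounds,
N-nitrosamines, aflatoxin-like fused bisfurans. Matches never alter the
numbers; they mark the record out-of-domain, are surfaced in every report,
and drive a distinct non-zero CLI exit code.

Salts and mixtures (multi-fragment SMILES) are rejected with a structure
error rather than auto-stripped: the model treats exactly one volatile
species per record. Molecules are canonicalized once on ingest; all SMARTS
matching runs on the canonical form, making classification independent of
the input SMILES writing.

## TTC values

| hazard label | TTC (μg/day) | basis |
|---|---|---|
| mutagen | 12 | less-than-lifetime (<30 day) mutagenic TTC at ~1e-6 excess risk |
| Cramer III | 90 | Kroes TTC, high structural concern |
| Cramer II | 540 | Kroes TTC, intermediate concern |
| Cramer I | 1800 | Kroes TTC, low concern |

The table is overridable in configuration; defaults are exactly these.
These thresholds derive from chronic oral exposure data and are therefore
conservative for single or brief inhalation exposures; the extrapolation
from oral to inhalation bioavailability is a documented limitation of the
approach, not of this implementation.

## Headspace physics

`headspace mass (μg) = VP(mmHg)·c·MW·V·10⁶ / (R·T)` with `c` the
mmHg→atm conversion. Two constants modes:

* `paper_printed` (default): R = 0.082 L·atm/(K·mol), c = 0.001316 —
  the rounded constants of the reference worked example, so its printed
  values (546 μg, 98.9 %) reproduce exactly;
* `high_precision`: R = 0.082057, c = 1/760.

The modes agree within 0.2 %. Defaults: V = 0.1 L, T = 298 K, one
headspace volume inhaled per day (`exposures_per_day`, configurable).
Vapor pressures are defined at 25 °C, so a non-298 K temperature logs a
warning rather than silently rescaling. Worked-example tests use a 0.5 %
relative tolerance, absorbing the reference's rounding.

For solutions the solute mole fraction is computed per 100 g of solution:
`n_chem = conc/MW`, `n_solv = Σ (100−conc)·w_i/MW_i` over solvent
components. The mol/L formulation of Raoult's law reduces to this under
the equal-volume cancellation, and the mass basis needs no density data
while reproducing the neat (x = 1) limit exactly. Built-in solvents: water
(18.02 g/mol), propylene glycol (76.09), and 50:50 ethanol/water read as a
**mass** ratio (46.07 and 18.02 at 0.5 each) — the mass/volume ambiguity
of "50 % ethanol" is resolved mass-wise and is configurable by
constructing a custom `Solvent`.

Activity coefficients, temperature dependence of VP, and co-solute
interactions are out of scope (ideal behavior throughout). Vapor pressure
is an *input*: a tolerant parser for EPI Suite/MPBPWIN-style text reports
extracts the predicted 25 °C value, preferring an experimental database
value when the report carries one.

## Validation harness

NOAEC (mg/m³) → NOAEL (μg/day) uses the default rat breathing rate
0.2 L/min for 360 min/day (72 L/day); both factors are per-record fields.
The margin compares that NOAEL with the headspace exposure at the
*recommended* concentration in a given solvent (neat mass for capped
chemicals, where the mole fraction is 1 and the margin is
solvent-independent). The daily-dose comparison deliberately aligns a
repeat-dose experimental NOAEL with the model's once-daily acute exposure —
a faithful reproduction of the validation design this harness implements.
Margins ≥ 1 mean the recommendation is health-protective.

Per-solvent summaries report the geometric mean over finite positive
margins (zero-exposure chemicals yield +inf margins, excluded from the
mean and counted separately), min/max, strict counts below 1 and below 10
(the <10 count includes the <1 chemicals), and the complementary
percentage representations (% ≥ 1, % ≥ 10), since both conventions appear
in practice.

## Synthetic panels

The fixture generator emulates a screening campaign: structures drawn from
a curated 27-entry library (alkanols/esters/hydrocarbons → Class I,
terpenoid and other saturated cyclic ethers → Class II, heteroaromatics and
N-bearing aliphatics → Class III, nitroaromatics/epoxides/haloalkanes →
mutagen, one N-nitrosamine and one organophosphate → out-of-domain), vapor
pressures log-uniform over 10⁻⁶–10² mmHg, molecular weights taken from the
structures themselves. Every library entry's class and traversal path were
verified by hand-tracing the shipped question table during development and
are stored with the entry.

Expected screening numbers come from a straight-line arithmetic oracle
embedded in the generator, with its own copies of the constants; the
module never imports the hazard/headspace/screening logic (enforced by a
test), so pipeline-vs-oracle agreement is a genuine two-route check.
Optional tox data back-solves NOAECs so the water-solvent margins hit
requested strata (<1, 1–10, >10) exactly.

What the panels do **not** emulate: any correlation between structure and
volatility, realistic NOAEC magnitudes, or chemistry outside the curated
library. Green tests on synthetic panels demonstrate internal correctness
of the arithmetic and rulebook traversal, not predictive performance on
real chemicals — the latter is what the NOAEC validation harness measures
when an experimental panel is supplied. Problem sizes in the shipped tests
(panels of 8–20, the 10-chemical reference panel at seed 42) keep the
whole suite in the seconds range.

## Numerical and reporting choices

* Concentrations are reported to 3 significant figures at the file
  boundary; full precision is kept internally.
* The 100 % cap is explicit and flagged (`capped`), since the TTC
  inversion exceeds 100 for low-volatility chemicals; capped ⇔ neat
  exposure ≤ TTC.
* Output CSVs begin with a `# key = value` metadata block (package
  version, rulebook versions + checksums, scenario, config hash) and are
  byte-stable for identical inputs; readers skip `#` lines so outputs
  round-trip.
* Column names carry units (`vp_mmHg`, `noaec_mg_m3`, `max_conc_pct_ww`).
* CLI exit codes: 0 clean, 2 load error, 3 out-of-domain or errored
  records present.

## Known limitations

* The condensed Cramer encoding can diverge from Toxtree's revised tree
  outside the odorant-like space; use overrides for authoritative
  classifications.
* The mutagenicity alert list is sensitive by design; specific alerts
  (SA11, SA28) over-flag some food-like chemicals.
* Ideal-gas and ideal-solution assumptions; no irritation, sensitization
  or asthmagenicity endpoints; TTC extrapolated from oral data.
* One volatile solute per record; no mixture headspace aggregation.
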