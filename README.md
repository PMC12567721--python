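# odorsafe

In silico inhalation-toxicity screening for volatile odorants in solution.

Researchers who ask human volunteers to sniff the headspace of a vial — for
example in psychophysical studies of novel odorants — routinely face
chemicals with no experimental toxicity data. `odorsafe` turns a chemical
structure (SMILES) plus a vapor pressure into a toxicology-based **maximum
solution concentration**: the strongest solution whose equilibrium headspace,
inhaled once per day, cannot deliver more than a hazard-based Threshold of
Toxicological Concern (TTC).

## The model

For each chemical the pipeline:

1. **Classifies hazard from structure.** SMARTS structural alerts for
   bacterial (Ames) mutagenicity (after the ISS / Benigni–Bossa rule base)
   and a data-driven Cramer decision tree for systemic-toxicity concern are
   evaluated; the most severe prediction wins
   (mutagen > Cramer III > II > I). Cohort-of-concern classes
   (organophosphates, dioxins, alkyl azoxy compounds, N-nitrosamines,
   aflatoxin-like structures) are screened separately and flag the record
   **out of domain** — TTC screening must not be used for them.
2. **Assigns a TTC** (μg/day): mutagen → 12, Cramer III → 90,
   Cramer II → 540, Cramer I → 1800.
3. **Computes the neat headspace exposure** from the vapor pressure VP
   (mmHg at 25 °C), molecular weight MW and headspace volume V, assuming
   ideal-gas equilibrium:

   `headspace mass (μg) = VP·MW·V / (R·T)`

4. **Inverts the TTC into a concentration** (capped at 100 % w/w):

   `max conc (% w/w) = min(100, TTC · 100 / exposure)`

For solutions, ideal Raoult behavior scales VP by the solute mole fraction
(computed per 100 g of solution — no densities needed), which powers the
**validation harness**: experimental repeat-dose inhalation NOAECs (mg/m³)
are converted to daily NOAELs via the default rat breathing rate
(0.2 L/min × 360 min/day = 72 L/day), and per-solvent safety margins
`NOAEL / permitted exposure` are summarized by geometric mean, range and
counts below 1 and 10.

## Worked example

Rose oxide (CAS 16409-43-1), predicted VP 0.657 mmHg, in the default
scenario (0.1 L headspace, 298 K, once-daily exposure):

```python
from odorsafe import ChemicalRecord, screen_chemical

rec = ChemicalRecord(id="rose_oxide", name="rose oxide",
                     smiles="CC1CCOC(C1)C=C(C)C", mw=154.25, vp_mmHg=0.657)
res = screen_chemical(rec)
print(res.hazard.cramer_class,       # II
      res.hazard.ttc_ug_per_day,     # 540.0
      round(res.neat_headspace_mass_ug, 1),  # 545.8
      round(res.max_conc_pct_ww, 1))         # 98.9
```

No mutagenicity alerts fire; the Cramer tree assigns the intermediate class
(II, TTC 540 μg/day); the equilibrium headspace above the neat liquid holds
≈546 μg; and solutions up to 98.9 % w/w keep a once-daily sniff below the
TTC. The same numbers are available from the shell:

```bash
odorsafe classify "CC1CCOC(C1)C=C(C)C"
odorsafe screen -i chemicals.csv -o screened.csv
odorsafe validate -i chemicals.csv --tox noaecs.csv -s water \
    --margins-out margins.csv --summary-out summary.csv
odorsafe fixtures -n 20 --seed 42 -o panel.csv --tox-output panel_tox.csv
```

`screen` exits non-zero when a run contains out-of-domain or errored
records; their rows are still written but flagged.

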