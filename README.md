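# radiotlc

Simulation, data handling and qualification of a radio-TLC (thin-layer
chromatography) scanner for radiochemical purity (RCP) testing of
technetium-99m radiopharmaceuticals — with the hardware replaced by a
physics-based scan simulator.

The package covers the full computational chain of such an instrument:

- **`radiotlc.simulate`** — a detector/scan simulator: spots of activity on
  a strip, exponential decay, a Gaussian line-spread response for the
  collimator, and Poisson counting per channel dwell. Includes factories
  for the standard qualification scenarios (blank background, decay-series
  linearity, 5%-impurity repeatability, LOQ, nine-spot positional
  accuracy, paired method comparison).
- **`radiotlc.chromio`** — the acquisition-record CSV format: a fixed
  metadata header (batch, operator, scan range, acquisition time, solvent
  origin/front, timestamp), a `position_mm,counts` table, and a SHA-256
  footprint line covering every preceding byte. Parsing classifies records
  as `verified` / `failed` / `unhashed`.
- **`radiotlc.analyze`** — the integration layer: background-subtracted
  net areas and relative percentages, retention factor (Rf), SNR in the
  pharmacopoeial 2H/h convention, FWHM by interpolated half-maximum
  crossings, and single- or dual-strip RCP. Records with a failed
  footprint are refused.
- **`radiotlc.qualify`** — the qualification suite: background rate,
  linearity (Pearson r ≥ 0.99), repeatability (CV ≤ 5%), limit of
  quantification (SNR ≥ 10), working range (200 × LOQ rule), positional
  accuracy (Rf deviation ≤ 10%), and method-comparison statistics
  (Pearson, Shapiro-Wilk, Bland-Altman bias and limits of agreement).
- **`radiotlc.cli`** — the `radiotlc` command binding it all together.

## Command line

```sh
# simulate a qualification scenario and write a hashed record CSV
radiotlc simulate --scenario repeatability --seed 7 --out strip.csv

# check a record's SHA-256 footprint (exit 0 verified / 1 failed / 2 unhashed)
radiotlc verify strip.csv

# integrate with a region file (label,start_mm,end_mm,kind)
radiotlc analyze strip.csv --regions regions.csv --main-label main --out report.csv

# run the full qualification (6-row summary) or a single test
radiotlc qualify all --seed 1 --out qualification.csv
radiotlc qualify compare --seed 1

# print the centralized instrument defaults
radiotlc --show-config
```

All stochastic commands take `--seed`; identical seeds reproduce output
files byte for byte. Scenario overrides are plain `key = value` config
files (`--config`), and outputs embed version/seed/config-digest
provenance.

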