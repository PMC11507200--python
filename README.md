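# scarquant

Color-based detection, isolation and quantification of myocardial infarct and
diffuse cardiac fibrosis in histological section images.

Cardiac injury models (coronary ligation, cryoinjury) are routinely evaluated
by staining serial heart sections and measuring how much of each section is
scar. Each common stain renders the infarct in a characteristic RGB palette:
Masson's trichrome (MTS) turns collagen/scar blue against red muscle; TTC
leaves infarct off-white against deep-red viable myocardium; picrosirius red
(PSR) stains collagen saturated red against pale tissue; and in H&E the
infarct is subtly green-shifted. `scarquant` turns those color differences
into reproducible per-pixel rules, producing infarct and whole-tissue masks,
relative infarct size, physical areas, serial-section volumes, and diffuse
fibrosis fractions — driven entirely by command-line flags, so every result is
scriptable and recorded in a RunRecord JSON.

## The rules

For a pixel with 8-bit channels (R, G, B), classified only inside the tissue
mask (non-near-white pixels, min(R,G,B) < 230 by default):

| Stain | Infarct rule | Defaults |
|-------|--------------|----------|
| MTS | R ≤ r_limit and B/R ≥ br_ratio_min | r_limit = 150, br_ratio_min = 1.2 |
| TTC | stddev(R, G, B) ≤ std_max (sample stddev, n−1) | std_max = 20 |
| PSR | R − mean_GB ≥ thd, with mean_GB = (G + B)/2 | thd = 60 |
| H&E | two-step green reveal, then keep large dense green components | r_limit = 200, min component 0.1% of tissue |

The H&E reveal: step 1 zeroes any channel above `r_limit`; step 2 keeps only
green (R := 0, B := 0) where R < G or B < G and blacks out everything else,
leaving the infarct as a green region on a suppressed background.

Quantification follows the standard serial-section (Cavalieri-style)
bookkeeping: relative infarct size = 100·∑P_s/∑P_t %, area = Px²·∑P (Px in
µm/pixel, areas in mm²), and with section thickness h1 and removed-tissue
thickness h2, each section contributes V_si = A_si·h1 and V_rsi = A_si·h2 to
the totals V_Ts and V_Tt (removed tissue is assumed to carry the adjacent
section's cross-section).

## Worked example

Generate a synthetic MTS section with known ground truth, analyze it, and
compute a two-section stack volume:

```sh
$ scarquant make-fixture --stain mts --seed 1 --out fx
wrote fixture to fx (truth fraction 13.99%)

$ scarquant analyze --stain mts --image fx/section.png --outdir out
infarct 1804 px / tissue 12947 px = 13.9%

$ printf 'infarct_pixels,tissue_pixels\n830,10000\n830,10000\n' > stack.csv
$ scarquant volume --stack stack.csv --h1 5 --h2 10 --pixel-size 5 --outdir out
V_Ts = 0.0006225 mm3, V_Tt = 0.0075 mm3, relative infarct volume = 8.3%
```

The analyze step recovered the generator's 13.99% ground-truth infarct
fraction from the noisy image (1804 of 12947 tissue pixels); the volume step
shows the arithmetic: each section of 830 infarct pixels at 5 µm/pixel is
830·25 µm² = 0.02075 mm², times (h1 + h2) = 15 µm per section pitch, summed
over two sections — 8.3% of the tissue volume. Outputs land beside the run:
`*_infarct_mask.png`, `*_tissue_mask.png`, `*_overlay.png` and a
`*_run.json` RunRecord with the exact thresholds and pixel counts.

Other subcommands: `split` (cut a multi-section slide scan into bit-exact
single-section images, `--bounds 0:900,900:1800` or `--auto`), `fibrosis`
(diffuse-fibrosis percentage of an MTS section plus an isolated-fibrosis
image), and threshold overrides (`--thd`, `--std-max`, …) or a YAML
`--config` on any analysis.

The library mirrors the CLI: the stain rules are scikit-learn-style
estimators (`MTSClassifier(r_limit=150).predict(image)` → boolean mask) that
compose with `get_params`/`set_params`, with thin functions
(`classify_mts`, `tissue_mask`, `stack_volumes`, `fibrosis_pct`, …) on top.

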