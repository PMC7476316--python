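# ductchron

Build dated master chronologies of **axial resin-duct defense metrics**
from tree cores.

Axial resin ducts in conifer secondary xylem store and deliver oleoresin,
a major defense against bark beetles and pathogens. Because ducts are
permanently embedded in annual rings, counting and measuring them ring by
ring turns an increment core into a retrospective time series of a tree's
defense investment. The measurement itself is manual — an operator fits
ellipses to ducts in ImageJ on a scanned, crossdated core — but everything
after that is mechanical bookkeeping, and that is what this package does:

1. **parse** the per-core ImageJ "Results" export (areas in in², one row
   per duct, with zero-area "fake" measurements clicked at each ring
   boundary as delimiters);
2. **date** every duct by splitting the sentinel-delimited stream into
   rings and anchoring the first ring at the innermost measured year,
   handling ductless rings (one bare sentinel) and missing rings (two
   consecutive sentinels);
3. **cross-check** the dated ducts against the core's ring widths from a
   Tucson-format RWL file (ring-count, span and missing-ring agreement);
4. **compute** five defense metrics per core-year, and optionally add A/B
   cores of each tree together;
5. **compile** the master chronology CSV, with QC flagging of implausible
   values and quick-look plots.

## The metrics

For ring *y* of a core with duct areas $a_1,\dots,a_n$ (mm²), ring width
$w_y$ (mm) and average core width $c$ (mm, e.g. 5.15 for a standard
increment borer), with ring area $A_y = w_y \cdot c$:

| metric | definition | type |
|---|---|---|
| duct size (mm²) | $\bar a = \tfrac1n\sum a_i$ (NA if $n=0$) | unstandardized |
| duct production (no. yr⁻¹) | $n$ | unstandardized |
| total duct area (mm² yr⁻¹) | $T=\sum a_i$ | unstandardized |
| duct density (no. mm⁻² yr⁻¹) | $n / A_y$ | standardized |
| relative duct area (% of ring) | $100\,T / A_y$ | standardized |

Standardized metrics adjust for growth rate; a missing ring ($w_y = 0$)
has undefined density and relative area (stored as NA). When two cores of
one tree are combined, counts, total areas and ring areas are **summed**
and the ratios recomputed from the sums, which keeps
size × production = total exact and reduces zero-duct years.

## Worked example

The package ships a synthetic-core generator (known ground truth: ring
widths with a negative-exponential age trend + AR(1) noise, Poisson duct
counts at rate λ per mm² of ring area, lognormal duct sizes, injected
missing rings), so the full workflow runs without any real cores:

```sh
$ ductchron simulate --n-cores 2 --n-years 30 --seed 11 --out fixtures
fixtures/site.rwl
$ ductchron add-years --input fixtures/SYN001a.txt --first-year 1940 --out dated --verbose
SYN001a: 30 rings (1940-1969), 32 ducts
dated/SYN001a.csv
$ ductchron add-years --input fixtures/SYN001b.txt --first-year 1940 --out dated --verbose
SYN001b: 30 rings (1940-1969), 43 ducts
dated/SYN001b.csv
$ ductchron metrics --ducts dated --rwl fixtures/site.rwl --core-width 5.15 \
      --first-year 1940 --last-year 1969 --combine --out tree.csv --verbose
2 cores, 30 rows
tree.csv
$ head -4 tree.csv
sample_id,year,duct_size_mm2,duct_production,total_duct_area_mm2,duct_density_per_mm2,relative_duct_area_pct,ring_width_mm,ring_area_mm2
SYN001,1940,0.0330644,4,0.132258,0.129234,0.427307,6.01,30.9515
SYN001,1941,0.0337634,3,0.10129,0.08504,0.287124,6.85,35.2775
SYN001,1942,0.043963,7,0.307741,0.193071,0.848801,7.04,36.256
$ ductchron qc --master tree.csv | head -2
QC flags: 0
missing rings (for review): 0
```

Reading the 1940 row: the tree's two cores together held 4 ducts that
year (mean size 0.033 mm², total 0.132 mm²) in a combined ring area of
30.95 mm² (summed ring widths × 5.15 mm core width), giving a duct
density of 0.129 ducts mm⁻² and 0.43% of the ring occupied by ducts.

With real data, replace `fixtures/*.txt` with your ImageJ exports (one
`sampleID.txt` per core, stem matching the RWL series ID exactly) and
`site.rwl` with your crossdated ring-width file. The subcommands map onto
the manual workflow — `add-years` per core right after measuring it,
then `metrics` (optionally `--combine`), then `qc` and `plot`. A YAML
config (`--config`) can hold the shared parameters; flags override it.
Every `metrics` run writes a `.log` audit file beside the CSV.

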