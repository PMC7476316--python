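# Methods

This note documents the conventions, numerical choices and limitations of
the ductchron pipeline: how duct measurements become a dated chronology,
what the synthetic generator does and does not emulate, and where the
design was genuinely open.

## Input conventions

**ImageJ measurement files.** One delimited text table per core, required
column `Area` (case-insensitive; tab or comma delimited, tab preferred on
a tie), areas in square inches — ImageJ's scale is set from the scan DPI,
so in² is taken as the unit of record and never autodetected per file.
Conversion to mm² uses the exact factor 25.4² = 645.16. The filename stem
is the sample ID and must match the core's RWL series ID exactly
(case-sensitive: the trailing lowercase core letter, as in `SNF383La`,
is significant). The `Label` column and any extra statistics columns are
ignored.

**Sentinels.** A measurement with area ≤ the sentinel threshold (default
exactly 0 in²) is a ring-boundary "fake". The threshold is configurable
because a stray one-pixel click can round to a tiny nonzero value; as a
guard in the other direction, any *non*-sentinel area below 10⁻⁵ in²
(≈ 0.0065 mm², smaller than any plausible duct) triggers a warning to
check whether a fake was mis-recorded. The final entry of every file must
be a sentinel — an unterminated final ring would silently drop the
newest ring — and this is enforced at parse time.

**Tucson RWL files.** The ID occupies the first 8 columns; the rest of
each line is whitespace-tokenized (tolerant of the spacing variants that
different measurement programs emit). Up to three leading lines that fail
the numeric layout are skipped as optional headers. Precision is detected
per series from the terminal stop marker — 999 means raw integers are
hundredths of mm, −9999 thousandths — and a series without a marker is
assumed to be 0.01 mm, with a warning. Width 0 is a missing (locally
absent) ring and is preserved, never dropped. On write, widths are
rounded half-up at the declared precision (via decimal arithmetic, so
1.005 mm → 1.01 mm at 0.01 mm) with a warning whenever information is
lost.

## Year assignment

The measurement stream of one core is split into maximal runs of
non-sentinel areas, each closed by one sentinel; run *k* (0-based) is
assigned year `first_year + k`, where `first_year` is the user-supplied
innermost measured year. An empty run (two adjacent sentinels, or a
leading sentinel) is a year with zero ducts. The stream alone cannot
distinguish "ring present, no ducts" from "missing ring" — both are an
extra sentinel — so disambiguation is delegated to `verify_alignment`,
which checks the dated table against the ring-width series: the table
must end at the declared last year (one dropped or doubled sentinel
shifts every later year, so the ring count is the sharp test), every
duct year must lie within the series span, and a zero-width year must
hold zero ducts. Violations are *reported*, not raised: the intended
remedy is editing the source TXT file and re-running, and the report
tells the user where to look.

## Metrics

Per core-year: duct size = mean area (NA when there are no ducts), duct
production = count, total duct area = sum, ring area = ring width ×
average core width, duct density = production / ring area, relative duct
area = 100 × total / ring area. Choices worth stating:

* **Missing rings** (ring area 0) get NA density and relative area
  rather than 0 or ∞; production and total are retained. NA propagates
  honestly into downstream statistics, and the QC report lists these
  years for review.
* **Core width is constant per core** (the borer's average width, e.g.
  5.15 mm). Ring-level core-width variation (partially damaged cores) is
  out of scope.
* **Combining A/B cores** sums production, total duct area, ring width
  and ring area per year over the cores covering that year, then
  recomputes size, density and relative area from the sums. The
  alternative — averaging per-core ratios — was rejected because it
  breaks the size × production = total identity and does not reduce
  zero-duct years. The core letter is assumed to be the final character
  of the sample ID; duct size at tree level is defined as combined total
  / combined production even when the cores' coverage differs.
* Values are held at full float precision throughout and rounded only
  when the master CSV is written (6 significant digits, `%.6g`), which
  together with the stable sort makes rebuilds byte-identical.

Identity checks in the tests use a relative tolerance of 10⁻⁹; in
practice the pipeline satisfies them to machine precision because totals
are computed once and the ratios derived from them.

## Quality control

Plausibility rules are pure predicates with configurable thresholds:
duct size outside [0.001, 0.5] mm² (bracketing what a real duct can
measure on a sanded core), relative duct area above 100% (ducts cannot
exceed the ring), and any negative value. Values are flagged, never
clamped or removed. A per-core min/max/mean summary and a per-core line
plot of any metric support the eyeball check.

## Synthetic cores

The generator produces the full input set — ImageJ-style TXT, Tucson
RWL, ground-truth JSON — from a small stochastic model:

* ring width: `max(0, w₀·exp(−δ·t) + AR(1) noise)`, the classic shape of
  raw conifer ring series (defaults w₀ = 3 mm, δ = 0.02 yr⁻¹, AR
  coefficient 0.5, innovation SD 0.4 mm), quantized to 0.01 mm so the
  fixture RWL is lossless;
* duct count per ring: Poisson with mean λ × ring area, so λ *is* the
  expected duct density; default λ = 0.15 ducts mm⁻², which with a
  5.15 mm core leaves roughly 10–20% of years ductless — the
  zero-inflation a small-diameter core really shows;
* duct areas: lognormal (μ = −3.3, σ = 0.5 on the log-mm² scale, median
  ≈ 0.037 mm²) truncated below at 0.005 mm²;
* missing rings: injected with probability 0.02 per year (zero width,
  zero ducts, an extra sentinel in the TXT).

Fixture TXT files write areas with **6 decimal places in in²** (ImageJ's
decimal-places setting is user-configurable). This keeps the smallest
permitted duct (0.005 mm² = 7.75 × 10⁻⁶ in²) strictly positive after
rounding, so no synthetic duct can collapse into a sentinel; the
worst-case area error a round trip can introduce is half a least
significant digit, 0.5 × 10⁻⁶ × 645.16 ≈ 3.2 × 10⁻⁴ mm², and tests
compare recovered areas at exactly that tolerance.

What the generator does *not* emulate: climate signal or any
cross-correlation between cores (each core is independent, so crossdating
cannot be exercised), false rings, operator error in ellipse fitting,
within-ring duct positioning, and rot or damaged core segments. Passing
round-trip tests therefore demonstrates that the bookkeeping — parsing,
splitting, dating, metric arithmetic — is exact, not that the biology or
the measurement process is well modelled.

## Rate recovery and its standard error

As an end-to-end statistical check, the generative rate λ is re-estimated
from a pipeline-recovered chronology by least squares through the origin
of duct production on ring area: λ̂ = Σxy / Σx². Because counts are
Poisson-like, their variance grows with ring area, and the homoskedastic
OLS variance formula understates Var(λ̂) = λ Σx³/(Σx²)²; the package's
`estimate_duct_rate` therefore reports the heteroskedasticity-robust
(sandwich) standard error, √(Σx²r²)/Σx², which is consistent for this
data-generating process. With 500-ring cores, λ̂ falls within ±3 SE of
truth in ≈ 99% of simulations, as a 3-SE band should.

Problem sizes used by the verification script and acceptance tests —
1000 random streams for the splitter oracle, 100 collections per RWL
dialect, 100 simulated 60-year cores for the end-to-end round trip and
misalignment detection, 100 seeds × 500 rings for rate recovery — are
large enough that every percentage reported is a stable estimate while
the whole run stays in the seconds range.

## Known limitations

* Crossdating, detrending and chronology statistics (COFECHA-style) are
  upstream/downstream of this package by design.
* A duct chronology has no archival file standard; only CSV is emitted.
* The year-count alignment check requires the user-declared last year to
  be correct; compensating errors (one extra *and* one missing sentinel)
  cancel in the ring count and are only caught if they disturb the
  missing-ring or span rules.
* Series whose final genuine width equals a stop-marker value in the
  0.01 mm dialect (9.99 mm) are inherently ambiguous in Tucson format;
  the value is read as the marker, as every Tucson reader must.
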