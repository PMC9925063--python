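# coralkrige

Reconstruction of historical mass coral-bleaching extent as annual
probability surfaces, from point survey reports and satellite-style
thermal-stress data.

## The problem

Coral bleaching observations are point reports collected by a
decentralized mix of scientists, monitoring programs and volunteers.
Survey effort is geographically biased — the Caribbean and the Great
Barrier Reef are heavily observed, much of the Indo-Pacific is not — so
raw report counts are a poor measure of how much reef area actually
bleached in a given year. `coralkrige` converts point reports into
spatially explicit annual maps of the **probability of bleaching
occurrence** on the global 0.05° × 0.05° reef raster, for researchers
studying bleaching extent, thermal-stress thresholds and their change
over time.

## The method

1. **Report QC and gridding** (`report_db`). Reports carry an ordinal
   severity code (−1 unknown, 0 = <1 % bleached, 1 = 1–10 %, 2 = 10–50 %,
   3 = >50 %) and must at minimum include latitude, longitude, year,
   severity and source. Coordinates off the reef raster snap to the
   nearest reef cell by great-circle distance (capped, default 50 km).
   A cell is a **presence** for a year if it holds a report with
   severity > 1; mild and unknown reports are excluded.

2. **Thermal stress** (`thermal_stress`). Degree Heating Weeks from
   daily SST: HotSpot = max(0, SST − MMM), where MMM is the maximum
   climatological monthly mean; only HotSpots ≥ 1 °C accumulate;
   DHW(t) = Σ (trailing 84 days) HotSpot / 7, in °C·weeks.

3. **Pseudo-absences**. True "no bleaching" reports are scarce
   (the streetlight effect), so cells whose annual maximum DHW stays
   below a threshold (default **0.5 °C·weeks**, strict; alternatives 0,
   0.25, 1.0 supported by a sensitivity harness) become value-0
   observations. A cell that is both presence and thermally quiet stays
   a presence.

4. **Indicator kriging** (`variogram`, `kriging`). The binary
   presence/pseudo-absence indicator follows I(s) = μ + ε′(s) with
   unknown constant mean μ. Per region and year, an empirical indicator
   semivariogram is fitted automatically over nine model families
   (Spherical, Exponential, Gaussian, Matérn, Stein's Matérn, Circular,
   Linear, Bessel, Pentaspherical) by weighted least squares, keeping
   the smallest residual sum of squares. Ordinary kriging with the
   unit-sum weight constraint then predicts the probability of bleaching
   (clamped to [0, 1]) at every reef cell.

5. **Regions and fallback** (`pipeline`). Interpolation runs
   independently in four ocean regions (Caribbean, Indian, Pacific, East
   Pacific) and combines into a global map. A region-year with too few
   presences, too few pseudo-absences, or a variogram that will not fit
   falls back to the degenerate assignment: 1.0 at presence cells, 0.0
   elsewhere.

6. **Analysis** (`stats`). Welch two-sample t-tests (report cells vs all
   cells), mean annual-max DHW per probability bin (>90 %, >66–90 %,
   >50–66 %, >33–50 %, >10–33 %, ≤10 %), likely (>66 %) / very likely
   (>90 %) extent counts, and OLS trends of annual-mean DHW.

Because the real observational database and satellite SST product cannot
ship with the package, `synthetic_data` generates seeded worlds with
known ground truth — clustered reefs, seasonal SST with a warming trend
and discrete heatwaves, a logistic DHW→bleaching link, and a biased
observation process — against which every stage is tested.

## Worked example

```python
import coralkrige as ck

world = ck.make_world(seed=42)                     # synthetic study area
cfg = ck.PipelineConfig(
    years=(world.params.model_years[0], world.params.model_years[-1]),
    climatology_years=world.params.climatology_years,
)
result = ck.run_pipeline(world.reports, world.sst, world.mask,
                         regions=world.regions, config=cfg)
print(result.run_report[["year", "region", "provenance",
                         "n_presence", "n_absence", "family"]].head(8))
```

```
 year      region provenance  n_presence  n_absence   family
 2001   Caribbean     kriged           8         19 Gaussian
 2001 EastPacific   fallback           0         40
 2001      Indian   fallback           2         38
 2001     Pacific     kriged          11          7   Matern
 2002   Caribbean     kriged           8         13 Gaussian
 2002 EastPacific   fallback           0         39
 2002      Indian   fallback           4         17
 2002     Pacific   fallback           4         13
```

Each row is one region-year: whether it was kriged (enough presences,
pseudo-absences and variogram structure) or fell back to the degenerate
1.0/0.0 map, and the selected variogram family. The analysis layer then
summarizes extent and validates the maps against the reports:

```python
ext = ck.extent_summary(result.maps, world.mask.cells).set_index("metric")
print(f"likely (>66%) at least once:      {ext.loc['prob>0.66','fraction']:.1%}")
print(f"very likely (>90%) at least once: {ext.loc['prob>0.9','fraction']:.1%}")

located, _ = ck.snap_reports(ck.parse_reports(world.reports).reports,
                             world.mask, max_snap_km=cfg.max_snap_km)
pres = ck.presence_cells(located, 2003)
contrast = ck.compare_reports_vs_all(result.maps[2], pres)
print(f"2003 report cells vs all cells: {contrast.mean_x:.2f} vs "
      f"{contrast.mean_y:.2f} (Welch t = {contrast.t:.1f}, p = {contrast.p:.2e})")
```

```
likely (>66%) at least once:      52.0%
very likely (>90%) at least once: 45.5%
2003 report cells vs all cells: 1.00 vs 0.22 (Welch t = 29.1, p = 1.14e-73)
```

52 % of the synthetic reef cells were likely bleached at least once in
the five modelled years, and cells holding severe-bleaching reports have
far higher interpolated probabilities than the average reef cell — the
internal-consistency check applied to every modelled year.

The same stages are available from the shell:

```bash
coralkrige simulate --seed 42 --out world/
coralkrige qc   --reports world/reports.csv --mask world/mask.csv --out clean.csv --log qc.csv
coralkrige dhw  --sst world/sst.csv --mask world/mask.csv --baseline 1998-2000 --out dhw.csv
coralkrige run  --reports world/reports.csv --sst world/sst.csv --mask world/mask.csv --out out/
coralkrige stats --reports world/reports.csv --sst world/sst.csv --mask world/mask.csv --out stats/
```

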