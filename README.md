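# eitsbt

Breath-by-breath analysis of electrical impedance tomography (EIT)
recordings around a spontaneous breathing trial (SBT).

When a mechanically ventilated patient is tested for weaning readiness
(e.g. a T-piece trial), continuous EIT provides a surrogate view of what
the lungs do: the **end-expiratory lung impedance (EELI)** tracks
end-expiratory lung volume, the tidal impedance swing **ΔZ** tracks
tidal volume, and the spatial distribution of the per-pixel tidal change
quantifies how (in)homogeneously the lung ventilates.  `eitsbt` turns a
raw sequence of reconstructed pixel impedance maps (≈50 Hz), a lung
mask, a 1 Hz ventilator log and the SBT phase timestamps into tidy
per-breath, per-stable-period and per-epoch parameter tables.

## What it computes

From each detected breath (end-expiration trough → end-inspiration
peak → next trough) on the artifact-cleaned global lung signal:

* EELI [AU] and ΔZ [AU], respiratory rate RR = 60/duration,
* calibrated tidal volume VT = c·ΔZ [ml] (c from a single- or
  multi-point match against the pre-SBT ventilator volumes), minute
  volume MV = RR·VT, and the rapid shallow breathing index
  RSBI = RR / VT[L],
* the **global inhomogeneity index**

  GI = Σ₍x,y∈lung₎ |DIₓᵧ − median(DI_lung)| / Σ₍x,y∈lung₎ DIₓᵧ

  where DIₓᵧ is the pixel tidal impedance change (GI = 0 ⇔ perfectly
  homogeneous ventilation),
* the **center of ventilation** (impedance-weighted centroid, % of the
  lung extent along the left–right and ventral–dorsal axes),
* **silent spaces**: lung pixels with DI below 10% of the maximum,
  split at the gravity-axis CoV line into nondependent (NSS) and
  dependent (DSS) parts, and the **functional lung space**
  FLS = 100% − silent%,
* left/right and ventral/dorsal ventilation fractions.

The SBT span is divided into five equal time epochs (plus the pre- and
post-SBT phases); parameters are averaged per epoch over automatically
selected *stable tidal breathing periods*, and EELI/ΔZ are reported as
percent change from the pre-SBT baseline.  A bundled synthetic-session
generator with full ground truth (amplitude maps, breath boundaries,
EELI track, artifact logs, exact ml-per-AU constant) backs every stage
with parameter-recovery tests.

## Worked example

Generate the packaged reference scenario (RR 15→25/min, EELI −20%
during the trial with incomplete recovery, ΔZ −15% with full recovery,
cardiac oscillation at 90/min, 1% spike artifacts) and run the full
pipeline:

```sh
eitsbt generate --preset recovery --seed 11 --out session.h5
eitsbt run --session session.h5 --outdir results
```

which prints

```
phase  n_breaths  eeli_mean  dz_mean   rr_mean  gi_mean  pct_change_eeli  pct_change_dz
  pre         31  39.994107 3.964963 15.307213 0.362111         0.000000       0.000000
sbt_1         25  32.515662 3.292859 25.026173 0.626437       -18.698867     -16.951091
sbt_2         25  32.006216 3.387009 25.000430 0.600132       -19.972670     -14.576528
sbt_3         25  32.000832 3.395885 25.000430 0.611242       -19.986132     -14.352674
sbt_4         25  32.002419 3.393186 25.000430 0.610053       -19.982164     -14.420753
sbt_5         25  32.000536 3.416076 24.992268 0.601907       -19.986873     -13.843440
 post         29  35.845432 4.042130 14.991159 0.357165       -10.373216       1.946223
```

Reading the table: at trial start the end-expiratory level drops by
~20% (derecruitment) and stays depressed after reconnection (−10%),
while the tidal swing drops ~15% and returns to baseline — the
characteristic dissociation between end-expiratory volume and tidal
volume around a T-piece trial.  The respiratory rate doubles from 15 to
25/min and the GI rises from 0.36 to ~0.6 during the trial.  The output
directory additionally holds `breaths.csv`, `periods.csv`,
`epochs.csv`, `qc_report.csv` and `session.log`; per-session epoch
tables from several patients can be stacked with `eitsbt cohort` into a
long-format table ready for mixed-model statistics in any stats
package.

The same pipeline is available as a library:

```python
import eitsbt as e

seq, mask, vent, ann, truth = e.generate_scenario(e.success_scenario(seed=42))
cleaned, filtered, breaths, periods, report = e.preprocess(seq, mask)
cal = e.calibrate_volume(periods[0].breaths, vent, fs=seq.fs)
table = e.parameters_table(cleaned, breaths, mask, cal)
```

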