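"""Generate a small synthetic SBT cohort and inspect its structure.

The generator emulates the statistical shape of a weaning-trial cohort:
per-second vitals with group-specific Poincaré geometry, 62.5 Hz
waveforms whose entropy differs between outcome groups, and per-breath
ventilator series that determine each patient's RSBI.
"""

from weanwave.synthetic import CohortSpec, gen_cohort
from weanwave.variability import rsbi

spec = CohortSpec(n_success=10, n_failure=6, sbt_duration=300.0, seed=3)
records, manifest = gen_cohort(spec)

rec = records[0]
print(f"{len(records)} records "
      f"({sum(r.label == 'success' for r in records)} success / "
      f"{sum(r.label == 'failure' for r in records)} failure)")
print(f"first patient: {rec.patient_id}, label={rec.label}")
print(f"  waveforms: {sorted(rec.waveforms)} at "
      f"{rec.waveforms['ECG'].sampling_rate} Hz")
print(f"  vitals:    {sorted(rec.numerics)} at 1 Hz")
print(f"  breaths:   {len(rec.breaths)} over {rec.sbt_duration:.0f} s "
      f"-> RSBI = {rsbi(rec.breaths, rec.sbt_duration):.1f} breaths/min/L")

print("\nmanifest (true generator parameters, first rows):")
cols = ["patient_id", "label", "hr.ratio", "ecg.noise_frac", "breaths.resp_rate"]
print(manifest[cols].head(5).to_string(index=False))
print("\nEvery drawn parameter is recorded, so expected feature values can")
print("be recomputed for any patient.")
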