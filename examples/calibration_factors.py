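"""Calibration-factor algebra: unit kinds, sensitivity, duration rescaling.

A SPECT calibration factor ties reconstructed counts to activity, but only
together with the total acquisition duration it was measured over.  This
example reproduces two worked conversions from a phantom calibration and
re-expresses a factor for a patient protocol with a different dwell time.
"""

from dosekit import AcquisitionMeta, CalibrationFactor, sensitivity_cps_per_MBq

# NEMA-phantom bottle scan: 60 projections x 120 s
bottle = CalibrationFactor(13.6e-6, "MBq_per_count", AcquisitionMeta(60, 120.0))
print(f"bottle factor  : 13.6e-6 MBq/count over 7200 s")
print(f"  sensitivity  : {sensitivity_cps_per_MBq(bottle):.2f} cps/MBq  (expected ~10.21)")

# sphere scan: 60 projections x 45 s
sphere = CalibrationFactor(38.3e-6, "MBq_per_count", AcquisitionMeta(60, 45.0))
print(f"sphere factor  : 38.3e-6 MBq/count over 2700 s")
print(f"  sensitivity  : {sensitivity_cps_per_MBq(sphere):.2f} cps/MBq  (expected ~9.67)")

# patient scans use 45 s per projection: rescale the bottle factor
patient = AcquisitionMeta(60, 45.0)
rescaled = bottle.rescale_for_duration(patient)
print(f"bottle factor rescaled to 45 s/projection: "
      f"{rescaled.magnitude * 1e6:.2f}e-6 MBq/count")
print(f"  sensitivity unchanged: {sensitivity_cps_per_MBq(rescaled):.2f} cps/MBq")

# unit kinds are exactly interconvertible
as_bq = sphere.as_unit("Bq_per_count")
print(f"sphere factor as Bq/count: {as_bq.magnitude:.2f} "
      f"(round-trips to {as_bq.as_unit('MBq_per_count').magnitude:.3e} MBq/count)")
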