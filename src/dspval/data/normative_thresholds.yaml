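# Normative thresholds for lower-limb nerve conduction parameters, as used by
# the Toronto General Hospital electrophysiology reference ranges (values
# roughly at the 1st/99th percentile of healthy distributions).
#
# direction: abnormal_low  -> a value BELOW the cutoff is abnormal
#            abnormal_high -> a value ABOVE the cutoff is abnormal
# A value exactly at the cutoff is NORMAL (the normal range is inclusive).
#
# Stratified parameters list one stratum per covariate interval; bounds are
# "le"/"gt" (age, years) or "ge"/"lt" (height, metres). Units: amplitudes in
# µV (sural) or mV (motor nerves), velocities in m/s, latencies in ms;
# summed amplitudes are in arbitrary units (µV + mV added numerically).
#
# Note: an empirically derived alternative cutoff of 58.5 ms for the tibial
# F-wave latency is in circulation; override via NormativeReference.with_override
# or a custom table if that convention is wanted.

sural_amp:
  direction: abnormal_low
  units: uV
  strata:
    - {covariate: age, le: 65, cutoff: 7.2}
    - {covariate: age, gt: 65, cutoff: 5.5}

sural_cv:
  direction: abnormal_low
  units: m/s
  strata:
    - {cutoff: 40.0}

peroneal_amp:
  direction: abnormal_low
  units: mV
  strata:
    - {covariate: age, le: 65, cutoff: 5.0}
    - {covariate: age, gt: 65, cutoff: 3.0}

peroneal_cv:
  direction: abnormal_low
  units: m/s
  strata:
    - {cutoff: 40.0}

peroneal_fwave:
  direction: abnormal_high
  units: ms
  strata:
    - {covariate: height, ge: 1.829, cutoff: 59.0}
    - {covariate: height, lt: 1.829, cutoff: 58.0}

tibial_amp:
  direction: abnormal_low
  units: mV
  strata:
    - {cutoff: 10.0}

tibial_cv:
  direction: abnormal_low
  units: m/s
  strata:
    - {cutoff: 40.0}

tibial_fwave:
  direction: abnormal_high
  units: ms
  strata:
    - {cutoff: 55.0}

sum_amp:
  direction: abnormal_low
  units: arbitrary
  strata:
    - {covariate: age, le: 65, cutoff: 17.2}
    - {covariate: age, gt: 65, cutoff: 15.5}

sum_cv:
  direction: abnormal_low
  units: m/s
  strata:
    - {cutoff: 120.0}

sum_fwave:
  direction: abnormal_high
  units: ms
  strata:
    - {covariate: height, ge: 1.829, cutoff: 114.0}
    - {covariate: height, lt: 1.829, cutoff: 113.0}
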