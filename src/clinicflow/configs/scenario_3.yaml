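admission_duration: 220.0
admission_start: 450.0
classes:
  followup_outpatient:
    first_physician: experienced_resident
    mix_probability: 0.08
    p_consult_senior: 0.46
    p_paraclinic: 0.28
  followup_prev_inpatient:
    first_physician: novice_resident
    mix_probability: 0.87
    p_consult_senior: 0.46
    p_paraclinic: 0.28
  new:
    first_physician: experienced_resident
    mix_probability: 0.05
    p_consult_senior: 0.46
    p_paraclinic: 0.28
interarrival:
  family: truncated_normal
  lower_bound: 0.0
  mean: 4.2
  sd: 5.8
n_replications: 1000
overtime: true
paraclinic_return: false
stations:
  cash:
    discipline: fifo
    schedule:
      duration: 480.0
      n_servers: 1
      start_time: 450.0
    service:
      family: lognormal
      lower_bound: 0.0
      mean: 0.2
      sd: 0.3
  experienced_resident:
    discipline: fifo
    schedule:
      duration: 260.0
      n_servers: 1
      start_time: 540.0
    service:
      family: lognormal
      lower_bound: 0.0
      mean: 4.91
      sd: 0.93
  novice_resident:
    discipline: fifo
    schedule:
      duration: 260.0
      n_servers: 2
      start_time: 540.0
    service:
      family: lognormal
      lower_bound: 0.0
      mean: 3.46
      sd: 2.06
  paraclinic:
    discipline: fifo
    schedule:
      duration: 480.0
      n_servers: 1
      start_time: 450.0
    service:
      family: lognormal
      lower_bound: 0.0
      mean: 20.0
      sd: 10.0
  registration:
    discipline: fifo
    schedule:
      duration: 480.0
      n_servers: 1
      start_time: 450.0
    service:
      family: lognormal
      lower_bound: 0.0
      mean: 1.13
      sd: 0.44
  senior_staff:
    discipline: fifo
    schedule:
      duration: 100.0
      n_servers: 1
      start_time: 645.0
    service:
      family: lognormal
      lower_bound: 0.0
      mean: 4.2
      sd: 0.93
weights:
  experienced_resident: 2.0
  novice_resident: 2.0
  senior_staff: 1.0
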