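# Waiting-time-reduction scenarios as field-path deltas on the base config.
# Times are minutes since midnight; durations are minutes.
scenarios:
  - id: 0
    label: "Base case (current clinic)"
    deltas: []
  - id: 1
    label: "Novice residents 2 -> 3"
    deltas:
      - {path: stations.novice_resident.schedule.n_servers, value: 3}
  - id: 2
    label: "Experienced residents 1 -> 2"
    deltas:
      - {path: stations.experienced_resident.schedule.n_servers, value: 2}
  - id: 3
    label: "Residents attend 10:00 -> 09:00, 200 -> 260 min"
    deltas:
      - {path: stations.novice_resident.schedule.start_time, value: 540}
      - {path: stations.novice_resident.schedule.duration, value: 260}
      - {path: stations.experienced_resident.schedule.start_time, value: 540}
      - {path: stations.experienced_resident.schedule.duration, value: 260}
  - id: 4
    label: "Senior staff attends 10:45 -> 10:00, 100 -> 160 min"
    deltas:
      - {path: stations.senior_staff.schedule.start_time, value: 600}
      - {path: stations.senior_staff.schedule.duration, value: 160}
  - id: 5
    label: "Admission opens 07:30 -> 08:00"
    deltas:
      - {path: admission_start, value: 480}
  - id: 6
    label: "Scenarios 1 + 2"
    deltas:
      - {path: stations.novice_resident.schedule.n_servers, value: 3}
      - {path: stations.experienced_resident.schedule.n_servers, value: 2}
  - id: 7
    label: "Scenarios 3 + 4"
    deltas:
      - {path: stations.novice_resident.schedule.start_time, value: 540}
      - {path: stations.novice_resident.schedule.duration, value: 260}
      - {path: stations.experienced_resident.schedule.start_time, value: 540}
      - {path: stations.experienced_resident.schedule.duration, value: 260}
      - {path: stations.senior_staff.schedule.start_time, value: 600}
      - {path: stations.senior_staff.schedule.duration, value: 160}
  - id: 8
    label: "Scenarios 1 + 2 + 5"
    deltas:
      - {path: stations.novice_resident.schedule.n_servers, value: 3}
      - {path: stations.experienced_resident.schedule.n_servers, value: 2}
      - {path: admission_start, value: 480}
  - id: 9
    label: "Scenarios 3 + 4 + 5"
    deltas:
      - {path: stations.novice_resident.schedule.start_time, value: 540}
      - {path: stations.novice_resident.schedule.duration, value: 260}
      - {path: stations.experienced_resident.schedule.start_time, value: 540}
      - {path: stations.experienced_resident.schedule.duration, value: 260}
      - {path: stations.senior_staff.schedule.start_time, value: 600}
      - {path: stations.senior_staff.schedule.duration, value: 160}
      - {path: admission_start, value: 480}
  - id: 10
    label: "Scenarios 1 + 2 + 3 + 4"
    deltas:
      - {path: stations.novice_resident.schedule.n_servers, value: 3}
      - {path: stations.experienced_resident.schedule.n_servers, value: 2}
      - {path: stations.novice_resident.schedule.start_time, value: 540}
      - {path: stations.novice_resident.schedule.duration, value: 260}
      - {path: stations.experienced_resident.schedule.start_time, value: 540}
      - {path: stations.experienced_resident.schedule.duration, value: 260}
      - {path: stations.senior_staff.schedule.start_time, value: 600}
      - {path: stations.senior_staff.schedule.duration, value: 160}
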