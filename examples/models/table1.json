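{
  "nodes": [
    {
      "id": "C0",
      "variable": "C",
      "time": 0,
      "role": "covariate"
    },
    {
      "id": "U0",
      "variable": "U",
      "time": 0,
      "role": "unknown_cause"
    },
    {
      "id": "E1",
      "variable": "E",
      "time": 1,
      "role": "exposure"
    },
    {
      "id": "D2",
      "variable": "D",
      "time": 2,
      "role": "outcome"
    }
  ],
  "edges": [
    [
      "C0",
      "D2"
    ],
    [
      "C0",
      "E1"
    ],
    [
      "E1",
      "D2"
    ],
    [
      "U0",
      "D2"
    ],
    [
      "U0",
      "E1"
    ]
  ],
  "tables": {
    "C0": {
      "parents": [],
      "p1": {
        "": 0.5
      }
    },
    "U0": {
      "parents": [],
      "p1": {
        "": 0.5
      }
    },
    "E1": {
      "parents": [
        "C0",
        "U0"
      ],
      "p1": {
        "C0=0,U0=0": 0.1,
        "C0=0,U0=1": 0.2,
        "C0=1,U0=0": 0.3,
        "C0=1,U0=1": 0.5
      }
    },
    "D2": {
      "parents": [
        "C0",
        "U0",
        "E1"
      ],
      "p1": {
        "C0=0,U0=0,E1=0": 0.1,
        "C0=0,U0=0,E1=1": 0.2,
        "C0=0,U0=1,E1=0": 0.1,
        "C0=0,U0=1,E1=1": 0.2,
        "C0=1,U0=0,E1=0": 0.15000000000000002,
        "C0=1,U0=0,E1=1": 0.30000000000000004,
        "C0=1,U0=1,E1=0": 0.4,
        "C0=1,U0=1,E1=1": 0.8
      }
    }
  },
  "cohort_size": 4000
}
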