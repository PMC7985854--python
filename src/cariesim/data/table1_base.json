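{
 "accuracy": {
  "radiograph": {
   "sensitivity": {
    "D1": {
     "high": 0.49,
     "kind": "triangular",
     "low": 0.24,
     "mode": 0.36
    },
    "D2": {
     "high": 0.7,
     "kind": "triangular",
     "low": 0.59,
     "mode": 0.64
    },
    "E2": {
     "high": 0.26,
     "kind": "triangular",
     "low": 0.21,
     "mode": 0.24
    }
   },
   "specificity": {
    "D1": {
     "high": 0.97,
     "kind": "triangular",
     "low": 0.89,
     "mode": 0.94
    },
    "D2": {
     "high": 0.98,
     "kind": "triangular",
     "low": 0.97,
     "mode": 0.98
    },
    "E2": {
     "high": 0.98,
     "kind": "triangular",
     "low": 0.95,
     "mode": 0.97
    }
   }
  },
  "radiograph_ai": {
   "sensitivity": {
    "D1": {
     "high": 0.68,
     "kind": "point",
     "low": 0.68,
     "mode": 0.68
    },
    "D2": {
     "high": 0.58,
     "kind": "point",
     "low": 0.58,
     "mode": 0.58
    },
    "E2": {
     "high": 0.68,
     "kind": "point",
     "low": 0.68,
     "mode": 0.68
    }
   },
   "specificity": {
    "D1": {
     "high": 0.86,
     "kind": "point",
     "low": 0.86,
     "mode": 0.86
    },
    "D2": {
     "high": 0.96,
     "kind": "point",
     "low": 0.96,
     "mode": 0.96
    },
    "E2": {
     "high": 0.86,
     "kind": "point",
     "low": 0.86,
     "mode": 0.86
    }
   }
  },
  "radiograph_primary_study": {
   "sensitivity": {
    "D1": {
     "high": 0.65,
     "kind": "triangular",
     "low": 0.19,
     "mode": 0.36
    },
    "D2": {
     "high": 0.7,
     "kind": "triangular",
     "low": 0.59,
     "mode": 0.64
    },
    "E2": {
     "high": 0.65,
     "kind": "triangular",
     "low": 0.19,
     "mode": 0.36
    }
   },
   "specificity": {
    "D1": {
     "high": 0.98,
     "kind": "triangular",
     "low": 0.69,
     "mode": 0.91
    },
    "D2": {
     "high": 0.98,
     "kind": "triangular",
     "low": 0.97,
     "mode": 0.98
    },
    "E2": {
     "high": 0.98,
     "kind": "triangular",
     "low": 0.69,
     "mode": 0.91
    }
   }
  },
  "visual_tactile": {
   "sensitivity": {
    "D1": {
     "high": 0.0,
     "kind": "point",
     "low": 0.0,
     "mode": 0.0
    },
    "D2": {
     "high": 0.353,
     "kind": "triangular",
     "low": 0.27,
     "mode": 0.311
    },
    "E2": {
     "high": 0.0,
     "kind": "point",
     "low": 0.0,
     "mode": 0.0
    }
   },
   "specificity": {
    "D1": {
     "high": 1.0,
     "kind": "point",
     "low": 1.0,
     "mode": 1.0
    },
    "D2": {
     "high": 0.945,
     "kind": "triangular",
     "low": 0.892,
     "mode": 0.922
    },
    "E2": {
     "high": 1.0,
     "kind": "point",
     "low": 1.0,
     "mode": 1.0
    }
   }
  }
 },
 "age_factor": 1.0,
 "clinical": {
  "capping_fraction": 0.95,
  "pulp_exposure_d3": 0.3,
  "pulp_exposure_rerestoration": 0.1,
  "replacement_probability": 0.8
 },
 "development": {
  "hazards": {
   "D1": {
    "a": 0.0426,
    "b": 0.0521,
    "base": 2.7
   },
   "D2": {
    "a": 0.024281999999999998,
    "b": 0.0521,
    "base": 2.7
   },
   "E2": {
    "a": 0.57252,
    "b": 0.1472,
    "base": 2.7
   }
  },
  "multipliers": {
   "D1": {
    "high": 1.29,
    "kind": "uniform",
    "low": 1.24,
    "mode": 1.26
   },
   "D2": {
    "high": 1.29,
    "kind": "uniform",
    "low": 1.24,
    "mode": 1.26
   },
   "E2": {
    "high": 1.29,
    "kind": "uniform",
    "low": 1.24,
    "mode": 1.26
   }
  }
 },
 "prevalence": {
  "high_multipliers": {
   "D1": 1.66,
   "D2": 1.66,
   "E2": 2.14
  },
  "low": {
   "D1": 0.025,
   "D2": 0.005,
   "E2": 0.14
  }
 },
 "progression": {
  "d2_to_d3_multiplier": 1.32,
  "infiltrated": {
   "D1": {
    "c": 68.869,
    "k": 2.078
   },
   "E2": {
    "c": 0.4289,
    "k": 1.391
   }
  },
  "infiltrated_multipliers": {
   "D1": {
    "high": 4.17,
    "kind": "triangular",
    "low": 0.23,
    "mode": 1.0
   },
   "E2": {
    "high": 5.15,
    "kind": "triangular",
    "low": 0.23,
    "mode": 1.0
   }
  },
  "risk_multiplier": {
   "high": 2.63,
   "low": 2.13
  },
  "untreated": {
   "D1": {
    "c": 161.52,
    "k": 2.078
   },
   "D2": {
    "c": 161.52,
    "k": 2.078
   },
   "E2": {
    "c": 3.0984,
    "k": 1.343
   }
  },
  "untreated_multipliers": {
   "D1": {
    "high": 1.13,
    "kind": "uniform",
    "low": 0.87,
    "mode": 1.0
   },
   "D2": {
    "high": 1.13,
    "kind": "uniform",
    "low": 0.87,
    "mode": 1.0
   },
   "E2": {
    "high": 1.13,
    "kind": "uniform",
    "low": 0.87,
    "mode": 1.0
   }
  }
 },
 "transitions": {
  "composite": {
   "allocation": {
    "composite": 0.45,
    "crown": 0.1,
    "extraction": 0.1,
    "rct": 0.25,
    "repair": 0.1
   },
   "probability": {
    "high": 0.016,
    "kind": "point",
    "low": 0.016,
    "mode": 0.016
   }
  },
  "crown_nonvital": {
   "allocation": {
    "extraction": 0.1,
    "recement": 0.2,
    "recrown": 0.6,
    "repair": 0.1
   },
   "probability": {
    "high": 0.029,
    "kind": "point",
    "low": 0.029,
    "mode": 0.029
   }
  },
  "crown_vital": {
   "allocation": {
    "extraction": 0.1,
    "rct": 0.25,
    "recement": 0.15,
    "recrown": 0.4,
    "repair": 0.1
   },
   "probability": {
    "high": 0.036,
    "kind": "point",
    "low": 0.036,
    "mode": 0.036
   }
  },
  "direct_capping": {
   "allocation": {
    "extraction": 0.05,
    "rct": 0.95
   },
   "probability": {
    "high": 0.111,
    "kind": "point",
    "low": 0.111,
    "mode": 0.111
   }
  },
  "implant": {
   "allocation": {
    "recrown": 0.2,
    "refix": 0.6,
    "reimplant": 0.2
   },
   "probability": {
    "high": 0.01,
    "kind": "point",
    "low": 0.01,
    "mode": 0.01
   }
  },
  "nonsurg_retreat": {
   "allocation": {
    "extraction": 0.75,
    "surg_retreat": 0.25
   },
   "probability": {
    "high": 0.085,
    "kind": "point",
    "low": 0.085,
    "mode": 0.085
   }
  },
  "rct": {
   "allocation": {
    "extraction": 0.5,
    "nonsurg_retreat": 0.2,
    "surg_retreat": 0.3
   },
   "probability": {
    "high": 0.021,
    "kind": "point",
    "low": 0.021,
    "mode": 0.021
   }
  },
  "surg_retreat": {
   "allocation": {
    "extraction": 1.0
   },
   "probability": {
    "high": 0.061,
    "kind": "point",
    "low": 0.061,
    "mode": 0.061
   }
  }
 }
}
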