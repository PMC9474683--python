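{
  "calibration": {
    "P212L": {
      "achieved": {
        "half_decay_s": 10.979999999999999,
        "half_rise_s": 1.5,
        "peak_drr0": 0.4400000378182196
      },
      "residuals": {
        "half_decay_s": -0.001818181818181941,
        "peak_drr0": 8.595049911696119e-08
      },
      "targets": {
        "half_decay_s": 11.0,
        "peak_drr0": 0.44
      }
    },
    "WT": {
      "achieved": {
        "half_decay_s": 7.379999999999999,
        "half_rise_s": 1.6999999999999993,
        "peak_drr0": 0.28000083630539324
      },
      "residuals": {
        "half_decay_s": -0.002702702702702885,
        "peak_drr0": 2.986804975767056e-06
      },
      "targets": {
        "half_decay_s": 7.4,
        "peak_drr0": 0.28
      }
    }
  },
  "generated_by": "scripts/build_presets.py",
  "genotypes": {
    "A112V": {
      "K_cam": 1.588046380061097,
      "baseline_ratio": 0.55,
      "ca_scale": 0.9,
      "fret_gain": 0.25,
      "genotype": "A112V",
      "hill_h": 4.0,
      "k_auto": 0.7074826477749397,
      "k_dephos": 0.05,
      "k_off": 0.35,
      "k_on": 1.0,
      "provenance": "WT preset with documented qualitative phenotype shifts"
    },
    "E109D": {
      "K_cam": 1.2099400990941693,
      "baseline_ratio": 0.55,
      "ca_scale": 0.8,
      "fret_gain": 0.25,
      "genotype": "E109D",
      "hill_h": 4.0,
      "k_auto": 0.8253964224040964,
      "k_dephos": 0.05,
      "k_off": 0.35,
      "k_on": 1.0,
      "provenance": "WT preset with documented qualitative phenotype shifts"
    },
    "E183V": {
      "K_cam": 1.6636676362544829,
      "baseline_ratio": 0.649,
      "ca_scale": 1.0,
      "fret_gain": 0.18,
      "genotype": "E183V",
      "hill_h": 4.0,
      "k_auto": 0.746787239317992,
      "k_dephos": 0.05,
      "k_off": 0.35,
      "k_on": 1.0,
      "provenance": "WT preset with documented qualitative phenotype shifts"
    },
    "F98S": {
      "K_cam": 1.179691596616815,
      "baseline_ratio": 0.55,
      "ca_scale": 1.0,
      "fret_gain": 0.25,
      "genotype": "F98S",
      "hill_h": 4.0,
      "k_auto": 0.8647010139471487,
      "k_dephos": 0.05,
      "k_off": 0.35,
      "k_on": 1.0,
      "provenance": "WT preset with documented qualitative phenotype shifts"
    },
    "H282R": {
      "K_cam": 1.1191945916621064,
      "baseline_ratio": 0.55,
      "ca_scale": 0.85,
      "fret_gain": 0.25,
      "genotype": "H282R",
      "hill_h": 4.0,
      "k_auto": 0.8489791773299278,
      "k_dephos": 0.05,
      "k_off": 0.35,
      "k_on": 1.0,
      "provenance": "WT preset with documented qualitative phenotype shifts"
    },
    "P212L": {
      "K_cam": 0.974164877747722,
      "baseline_ratio": 0.55,
      "ca_scale": 1.0,
      "fret_gain": 0.25,
      "genotype": "P212L",
      "hill_h": 4.0,
      "k_auto": 0.882990207900946,
      "k_dephos": 0.05,
      "k_off": 0.35,
      "k_on": 1.0,
      "provenance": "calibrated to printed somatic peak and half-decay"
    },
    "P212Q": {
      "K_cam": 1.028449084230044,
      "baseline_ratio": 0.55,
      "ca_scale": 1.0,
      "fret_gain": 0.25,
      "genotype": "P212Q",
      "hill_h": 4.0,
      "k_auto": 0.8804228505643695,
      "k_dephos": 0.05,
      "k_off": 0.35,
      "k_on": 1.0,
      "provenance": "WT preset with documented qualitative phenotype shifts"
    },
    "P235L": {
      "K_cam": 1.5124251238677116,
      "baseline_ratio": 0.55,
      "ca_scale": 1.0,
      "fret_gain": 0.25,
      "genotype": "P235L",
      "hill_h": 4.0,
      "k_auto": 0.7860918308610442,
      "k_dephos": 0.05,
      "k_off": 0.35,
      "k_on": 1.0,
      "provenance": "WT preset with documented qualitative phenotype shifts"
    },
    "T286P": {
      "K_cam": 1.0889460891847522,
      "baseline_ratio": 0.55,
      "ca_scale": 0.85,
      "fret_gain": 0.25,
      "genotype": "T286P",
      "hill_h": 4.0,
      "k_auto": 0.0,
      "k_dephos": 0.05,
      "k_off": 0.35,
      "k_on": 1.0,
      "provenance": "WT preset with documented qualitative phenotype shifts"
    },
    "WT": {
      "K_cam": 1.5124251238677116,
      "baseline_ratio": 0.55,
      "ca_scale": 1.0,
      "fret_gain": 0.25,
      "genotype": "WT",
      "hill_h": 4.0,
      "k_auto": 0.7860918308610442,
      "k_dephos": 0.05,
      "k_off": 0.35,
      "k_on": 1.0,
      "provenance": "calibrated to printed somatic peak and half-decay"
    }
  },
  "version": 1
}
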