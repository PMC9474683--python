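"""Regenerate src/camfret/data/presets.json.

Calibrates the WT and P212L presets against the printed somatic metrics
(peak dR/R0 and half-decay under 50 pulses at 20 Hz), derives the other
mutant presets from the documented qualitative shifts, and recalibrates
the simulator's memantine IC50 constant.  Run from the repository root:

    python scripts/build_presets.py
"""

import json
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from camfret.simulate import (  # noqa: E402
    CALIBRATION_TARGETS,
    KinaseModelParams,
    calibrate_memantine_ic50,
    calibrate_preset,
    derive_mutant_presets,
)


def main():
    results = {}
    for geno in ("WT", "P212L"):
        res = calibrate_preset(
            CALIBRATION_TARGETS[geno],
            KinaseModelParams(genotype=geno),
            free=("K_cam", "k_auto"),
        )
        results[geno] = res
        print(f"{geno}: K_cam={res.params.K_cam:.4f} k_auto={res.params.k_auto:.4f} "
              f"residuals={ {k: f'{v:+.2%}' for k, v in res.residuals.items()} }")

    table = derive_mutant_presets(results["WT"].params, results["P212L"].params)
    doc = {
        "version": 1,
        "generated_by": "scripts/build_presets.py",
        "calibration": {
            g: {"targets": results[g].targets, "achieved": results[g].achieved, "residuals": results[g].residuals}
            for g in results
        },
        "genotypes": table,
    }
    out = pathlib.Path(__file__).resolve().parents[1] / "src" / "camfret" / "data" / "presets.json"
    out.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    print(f"wrote {out}")

    ic50 = calibrate_memantine_ic50()
    print(f"memantine ic50_sim = {ic50:.4f} uM (update camfret.simulate.pharm.MEMANTINE_IC50_SIM if it moved)")


if __name__ == "__main__":
    main()
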