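#!/usr/bin/env python
"""Generate the synthetic study cohort.

Emulates the experimental design — volumes on days 1, 3, 6, 9, 13, 15;
adoptive transfer on day 3 or 7; four intravital positions per mouse on
days 6 and 9 (after transfer only) — for an untreated control group and
both fitted treatment groups, and writes the cohort tables used by the
downstream killing-model and calibration analyses.
"""

from pathlib import Path

from ctldyn.model import ModelParameters, load_params
from ctldyn.observation import write_cohort
from ctldyn.synthetic import CohortDesign, generate_cohort, write_manifest

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 20210524


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    design = CohortDesign(n_mice=5, seed=SEED)
    mice = generate_cohort(
        {"ACT-only": load_params("act_only"), "ACT+mAb": load_params("act_mab")},
        design, transfer_days=(3.0, 7.0),
    )
    mice += generate_cohort(
        {"no-ACT": ModelParameters(g=0.5, s=0.0)},
        CohortDesign(n_mice=5, seed=SEED + 1), transfer_days=(None,),
    )
    write_cohort(mice, OUT / "volumes.csv", OUT / "positions.csv")
    write_manifest(design, OUT / "manifest.yaml",
                   extra={"groups": ["ACT-only", "ACT+mAb", "no-ACT"],
                          "noise": True, "seed_untreated": SEED + 1})
    n_pos = sum(len(m.positions) for m in mice)
    print(f"wrote {len(mice)} mice ({n_pos} intravital positions) to {OUT}")


if __name__ == "__main__":
    main()
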