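#!/usr/bin/env python
"""Generate the two synthetic datasets the inference stages consume.

Writes a cross-sectional snapshot collection (60 embryos, fixation times
uniform on [0, 48] h then discarded, multinomial classification noise) and an
endpoint chimera titration panel (five conditions x 10 embryos) to results/.
"""

from pathlib import Path

from blastabc import SyntheticSpec, generate_chimera_panel, generate_dataset
from blastabc.model import DEFAULT_BASE_PARAMS, DEFAULT_CHIMERA_PARAMS

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

SEED = 123


def main() -> None:
    cross = generate_dataset(
        SyntheticSpec(DEFAULT_BASE_PARAMS, n_embryos=60, seed=SEED)
    )
    cross.to_csv(OUT / "synthetic_cross_sectional.csv")
    print(f"cross-sectional: {len(cross)} embryos, "
          f"columns {cross.count_columns}")
    print(cross.frame[["T", "C", "P", "E"]].describe().loc[["mean", "max"]].round(1))

    panel = generate_chimera_panel(
        DEFAULT_CHIMERA_PARAMS, n_per_condition=10, seed=SEED
    )
    panel.to_csv(OUT / "synthetic_chimera_panel.csv")
    by = panel.frame.groupby("condition")[["T", "P", "E_host", "E_donor"]].mean()
    print(f"\nchimera panel: {len(panel)} embryos; condition means:")
    print(by.round(1))


if __name__ == "__main__":
    main()
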