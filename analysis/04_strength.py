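#!/usr/bin/env python
"""Within- and between-alliance strength, bridge trios, first-order bonds.

For each period, computes the per-male strength table, checks which males
carry the highest normalized between-alliance strength (the designated
bridge trios, if the generator did its job), breaks bStrength down per
third-order partner, and tracks the mean HWI between first-order units.
Run 01 and 02 first.
"""

from pathlib import Path

from alliancenet.association import AssociationMatrix
from alliancenet.strength import (
    bstrength_by_partner,
    strength_table,
    unit_mean_hwi,
)
from alliancenet.survey_io import load_registry
from alliancenet.synthetic import preset_t1, preset_t3

OUT = Path(__file__).resolve().parent.parent / "results"
PRESETS = {"T1": preset_t1, "T3": preset_t3}


def main() -> None:
    for period, preset in PRESETS.items():
        outdir = OUT / f"sim_{period}"
        cfg = preset()
        matrix = AssociationMatrix.from_csv(outdir / "hwi.csv", period=period)
        registry = load_registry(outdir / "registry.yaml")
        table = strength_table(matrix, registry, period)
        table.to_csv(outdir / "strength.csv", index=False)
        per_partner = bstrength_by_partner(matrix, registry, period)
        per_partner.to_csv(outdir / "bstrength_by_partner.csv", index=False)

        print(f"[{period}]")
        for aid, unit in sorted(cfg.bridge_units.items()):
            if not cfg.partners_of(aid):
                continue
            sub = table[table.alliance == aid].sort_values(
                "bStrength_N", ascending=False
            )
            top = list(sub.head(3)["id"])
            print(
                f"  {aid}: top bStrength_N {top} "
                f"(designated bridge unit {sorted(unit)})"
            )
        # cohesion between the first first-order units of one alliance
        units = [u for u in cfg.alliances["PD"]]
        mean = unit_mean_hwi(matrix, sorted(units[0]), sorted(units[1]))
        print(
            f"  PD inter-unit mean HWI ({sorted(units[0])} vs "
            f"{sorted(units[1])}): {mean:.3f}"
        )


if __name__ == "__main__":
    main()
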