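#!/usr/bin/env python
"""Electromechanical design numbers for the bi-layer stretchable array.

Evaluates the closed forms at the device's design point: an 80 µm
recording site, the 45/30/30 µm PDMS layer stack, stimulation at up to
110 µA (200 µs per phase), and the measured impedances before/after
platinum-black electroplating and in vivo. Writes results/electromech.json.
"""

import json
from pathlib import Path

from pnisig import electromech as em

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    geom = em.ElectrodeGeom(diameter=80.0)
    stack = em.LayerStack()
    offsets = em.neutral_plane_offsets(stack)

    results = {
        "disc_area_um2": em.disc_area(geom),
        "current_density_110uA_mA_mm2": em.current_density(110.0, geom),
        "current_density_200uA_mA_mm2": em.current_density(200.0, geom),
        "charge_per_phase_110uA_133us_nC": em.charge_per_phase(110.0, 133.0),
        "impedance_fold_change_plating": em.fold_change(465.0, 20.0),
        "ohmic_voltage_100uA_75kohm_V": em.ohmic_voltage(100.0, 75.0),
        "neutral_plane_offsets_um": offsets,
        "bending_strain_at_250um_radius": {
            layer: em.bending_strain(d, 250.0) for layer, d in offsets.items()
        },
        "poisson_thickness_105um_20pct_strain_um": em.poisson_thickness(105.0, 0.20),
    }

    print("Electromechanical design point (80 µm site, 45/30/30 µm stack):")
    print(f"  site area:                {results['disc_area_um2']:.1f} µm²")
    print(f"  current density @110 µA:  {results['current_density_110uA_mA_mm2']:.1f} mA/mm²")
    print(f"  current density @200 µA:  {results['current_density_200uA_mA_mm2']:.1f} mA/mm²")
    print(f"  plating impedance drop:   {results['impedance_fold_change_plating']:.1f}×")
    print(f"  V = IZ @100 µA, 75 kΩ:    {results['ohmic_voltage_100uA_75kohm_V']:.1f} V (compliance 10 V)")
    print(f"  d_N (L1, L2):             {offsets['L1']:.1f}, {offsets['L2']:.1f} µm")
    print(f"  strain at BR 250 µm:      L1 {results['bending_strain_at_250um_radius']['L1']*100:.1f}%, "
          f"L2 {results['bending_strain_at_250um_radius']['L2']*100:.1f}%")

    OUT.mkdir(exist_ok=True)
    (OUT / "electromech.json").write_text(json.dumps(results, indent=1))
    print(f"wrote {OUT / 'electromech.json'}")


if __name__ == "__main__":
    main()
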