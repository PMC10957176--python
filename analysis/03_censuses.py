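"""Run the cellular censuses on the simulated measurements.

Volume from diameter, protein molecules per cell from the tryptophan
plate, and ribosomes per cell from the electropherogram pair (with
spike-in yield correction), then the protein-to-ribosome ratio.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from riboaccount import census as cen

ROOT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int) -> None:
    data = ROOT / "data"
    geom = cen.volume_from_diameter(7.3)  # resting-lymphocyte-like diameter

    plate = pd.read_csv(data / "trp_plate.csv")
    protein = cen.protein_census_from_plate(
        plate, sampled_fraction=0.02, n_cells=2e6, volume_fl=geom.volume_fl
    )

    ribo = cen.ribosome_census_from_traces(
        pd.read_csv(data / "electropherogram_sample.csv"),
        pd.read_csv(data / "electropherogram_standard.csv"),
        cen.DEFAULT_RRNA_WINDOWS,
        eluate_volume_ul=50.0,
        n_cells=1e6,
        organism="mouse",
    )

    out = {
        "volume": {"diameter_um": 7.3, "volume_fl": round(geom.volume_fl, 1)},
        "protein": {
            "mass_pg_per_cell": round(protein.mass_pg_per_cell, 2),
            "proteins_per_cell": round(protein.proteins_per_cell),
            "proteins_per_fl": round(protein.proteins_per_fl),
        },
        "ribosomes": {
            "copies_18s_per_cell": round(ribo.copies_18s_per_cell),
            "copies_28s_per_cell": round(ribo.copies_28s_per_cell),
            "functional_ribosomes_per_cell": round(ribo.functional_ribosomes_per_cell),
            "rna_yield": round(ribo.rna_yield, 4),
        },
        "protein_per_ribosome": round(
            protein.proteins_per_cell / ribo.functional_ribosomes_per_cell, 1
        ),
    }
    (ROOT / "census.json").write_text(json.dumps(out, indent=2) + "\n")
    print(
        f"{out['protein']['proteins_per_cell']:.3g} proteins and "
        f"{out['ribosomes']['functional_ribosomes_per_cell']:.3g} functional ribosomes "
        f"per cell -> P/R = {out['protein_per_ribosome']}"
    )


if __name__ == "__main__":
    p = argparse.ArgumentParser()
    p.add_argument("--seed", type=int, default=1)
    main(p.parse_args().seed)
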