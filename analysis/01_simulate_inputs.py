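"""Generate every synthetic input dataset with its ground-truth sidecar.

Emulates the five measurement types the pipeline consumes: an RPM
run-off time course, a Bioanalyzer electropherogram pair, a tryptophan
plate, a polysome profile, and a CFSE dilution time course. Outputs go
to results/data/.
"""

import argparse
from pathlib import Path

from riboaccount import synthetic as syn

OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main(seed: int) -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    events, truth = syn.gen_rta_events(
        syn.RtaSimSpec(
            t_half_s=70.0,
            stalled_frac=0.1,
            mean_signal=1000.0,
            background_mean=50.0,
            cv=0.4,
            chase_times_s=[0, 30, 60, 120, 180, 300, 600, 900],
            cells_per_timepoint=300,
            seed=seed,
        )
    )
    events.to_csv(OUT / "rta_events.csv", index=False)
    truth.write(OUT / "rta_truth.json")

    sample, standard, truth = syn.gen_electropherogram(
        syn.BioanalyzerSimSpec(
            copies_18s_per_cell=300e3,
            copies_28s_per_cell=264e3,
            n_cells=1e6,
            rna_yield=0.8,
            spike_in_ng=375.0,
            eluate_volume_ul=50.0,
            noise_sd=0.002,
            seed=seed + 1,
        )
    )
    sample.to_csv(OUT / "electropherogram_sample.csv", index=False)
    standard.to_csv(OUT / "electropherogram_standard.csv", index=False)
    truth.write(OUT / "bioanalyzer_truth.json")

    plate, truth = syn.gen_trp_plate(
        mass_per_cell_pg=36.3,
        n_cells=2e6,
        standards_ng_trp=[0, 5, 10, 20, 40],
        noise_sd=0.5,
        seed=seed + 2,
    )
    plate.to_csv(OUT / "trp_plate.csv", index=False)
    truth.write(OUT / "trp_truth.json")

    profile, truth = syn.gen_polysome_profile(
        frac_monosome=0.65, seed=seed + 3, noise_sd=0.005
    )
    profile.to_csv(OUT / "polysome_profile.csv", index=False)
    truth.write(OUT / "polysome_truth.json")

    cfse, truth = syn.gen_cfse_timecourse(
        syn.CfseSimSpec(
            initial_mfi=1e4,
            timepoints_hr=[0, 30, 48],
            doubling_time_hr=6.8,
            lag_hr=24.0,
            cv=0.3,
            cells_per_timepoint=1000,
            seed=seed + 4,
        )
    )
    cfse.to_csv(OUT / "cfse_timecourse.csv", index=False)
    truth.write(OUT / "cfse_truth.json")

    print(f"wrote 5 synthetic datasets with truth sidecars to {OUT}")


if __name__ == "__main__":
    p = argparse.ArgumentParser()
    p.add_argument("--seed", type=int, default=1)
    main(p.parse_args().seed)
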