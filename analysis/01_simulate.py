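"""Generate the matched synthetic study dataset.

Writes, under results/data/: the cohort table with latent senescence, the
per-cell biopsy classifications, the normalized urinary proteome with its
protein truth table, one spatial field, and the outcome records with eGFR
visit series.  All later analysis steps read these files.
"""

import json
from pathlib import Path

import pandas as pd

from senuro import core_io, proteomics_screen, synthetic_data

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 20250924

def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = synthetic_data.SimConfig(seed=SEED)

    participants, truth = synthetic_data.gen_cohort(cfg)
    truth.to_csv(OUT / "cohort.csv", index=False)

    cells = []
    for i, (p, s) in enumerate(zip(participants, truth["senescence_pct"])):
        cells.extend(
            synthetic_data.gen_biopsy_cells(
                float(s), n_cells=400, seed=SEED + i, participant_id=p.id
            )
        )
    core_io.write_cell_table(cells, OUT / "cells.csv")

    samples, protein_truth = synthetic_data.gen_proteome(
        truth["senescence_pct"], cfg
    )
    proteomics_screen.normalize(samples).to_csv(OUT / "proteome_normalized.csv")
    protein_truth.to_csv(OUT / "protein_truth.csv", index=False)

    field = synthetic_data.gen_spatial(cfg)
    field.to_csv(OUT / "spatial_cells.csv", OUT / "spatial_transcripts.csv")

    # the outcome arm runs at the outcome-cohort scale
    out_parts, out_truth = synthetic_data.gen_cohort(cfg, n=570)
    records, series = synthetic_data.gen_outcomes(out_parts, out_truth, cfg)
    out_truth.to_csv(OUT / "outcome_cohort.csv", index=False)
    records.to_csv(OUT / "outcome_records.csv", index=False)
    pd.DataFrame(
        [
            {"participant_id": pid, "day": d, "egfr": e}
            for pid, visits in series.items()
            for d, e in visits
        ]
    ).to_csv(OUT / "egfr_series.csv", index=False)
    rrt = {p.id: p.rrt_start for p in out_parts}
    death = {p.id: p.death for p in out_parts}
    followup = {p.id: p.last_followup for p in out_parts}
    pd.DataFrame(
        {
            "participant_id": list(rrt),
            "rrt_start": list(rrt.values()),
            "death": list(death.values()),
            "last_followup": list(followup.values()),
        }
    ).to_csv(OUT / "outcome_events.csv", index=False)

    (OUT / "seed.json").write_text(json.dumps({"seed": SEED}))
    print(f"biopsy cohort n={len(participants)}, outcome cohort n=570, "
          f"{len(cells)} classified cells, "
          f"{len(field.transcripts)} CLU transcripts -> {OUT}")

if __name__ == "__main__":
    main()
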