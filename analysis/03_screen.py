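"""Screen the normalized urinary proteome against tissue senescence.

Spearman correlation per protein with BH adjustment, then the shortlist
(adjusted p < 0.05, rho > 0.5) flagged against the packaged SASP list.
Writes results/candidates.csv and results/shortlist.csv.
"""

from pathlib import Path

import pandas as pd

from senuro import proteomics_screen as ps

BASE = Path(__file__).resolve().parent.parent / "results"

def main() -> None:
    matrix = pd.read_csv(BASE / "data" / "proteome_normalized.csv", index_col=0)
    senescence = pd.read_csv(BASE / "senescence.csv").set_index("participant_id")
    senescence = senescence.loc[matrix.index, "pct_senescent"]
    sasp = ps.load_sasp_list()

    candidates = ps.correlation_screen(matrix, senescence, sasp_list=sasp)
    candidates.to_csv(BASE / "candidates.csv", index=False)
    short = ps.shortlist(candidates, sasp_list=sasp)
    short.to_csv(BASE / "shortlist.csv", index=False)

    n_pos_sig = ((candidates.rho > 0) & (candidates.p_adj < 0.05)).sum()
    print(f"{len(candidates)} proteins screened; {n_pos_sig} positively "
          f"correlated at adjusted p<0.05; shortlist (rho>0.5):")
    print(short[["protein", "rho", "p_adj", "sasp_flag"]].to_string(index=False))

if __name__ == "__main__":
    main()
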