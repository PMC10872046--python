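"""Convert records to gridded presences and balance recording effort.

Deduplicates occurrence records into species x cell x period presences,
keeps the species with a southern T1 distribution center (< 7,000,000 N),
and equalizes T1/T2 presence totals within five latitudinal zones by
subsampling T2 five times.
"""

import json
import sys
import warnings
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import MASTER_SEED, N_REPLICATES, N_ZONES, PERIODS, RESULTS

import edgeshift as es
from edgeshift._seeds import subseed
from edgeshift.synthetic import STUDY_GRID


def main() -> None:
    occurrences = pd.read_csv(RESULTS / "occurrences.tsv", sep="\t")
    report: dict = {}
    presences = es.grid_presences(occurrences, STUDY_GRID, PERIODS, report)
    retained = es.filter_southern_species(presences, 7_000_000.0, report=report)
    presences = presences[presences["species_id"].isin(retained)]
    zones = es.ZonePartition.equal_width(STUDY_GRID.y_min, STUDY_GRID.y_max, N_ZONES)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        replicates = es.balance_effort(
            presences, zones, N_REPLICATES, seed=subseed(MASTER_SEED, "balance")
        )

    presences.to_csv(RESULTS / "presences.tsv", sep="\t", index=False)
    for rep in replicates:
        rep.presences.to_csv(
            RESULTS / f"replicate_{rep.index}.tsv", sep="\t", index=False
        )
    report["zone_counts"] = replicates[0].zone_counts.to_dict("records")
    (RESULTS / "prep_report.json").write_text(json.dumps(report, indent=1))

    zc = replicates[0].zone_counts
    print(f"{len(presences)} presences for {len(retained)} retained species "
          f"({len(report['removed_northern'])} removed as northern)")
    print("per-zone T1 / available T2 / kept T2:")
    for row in zc.itertuples(index=False):
        print(f"  zone {row.zone}: {row.n_T1:6d} / {row.n_T2_available:6d} / "
              f"{row.n_T2_kept:6d}")
    print(f"wrote {N_REPLICATES} balanced replicates")


if __name__ == "__main__":
    main()
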