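"""Target-search parameter table from the measured fractions and residence times.

Pure occupancy algebra: specific fraction = total − non-specific (mutant
control); τ_search = (1 − F_s)/F_s · τ_res; the search time splits between
free 3D diffusion and non-specific chromatin association in proportion to
the corresponding population fractions. Also reports the stroboscopic
motion-blur loss. Writes results/search_table.json.
"""

import json
from pathlib import Path

from smtk.replay import search_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = search_table()
    for name, row in table.items():
        print(name, json.dumps(row, default=float))
    OUT.mkdir(exist_ok=True)
    (OUT / "search_table.json").write_text(json.dumps(table, indent=1, default=float))


if __name__ == "__main__":
    main()
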