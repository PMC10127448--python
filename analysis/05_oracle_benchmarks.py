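#!/usr/bin/env python
"""Desk-scale oracle benchmarks over many random networks.

Smaller companion to scripts/acceptance.py: LP-vs-BFS distance agreement,
knockout-screen agreement with exhaustive cobrapy re-solves, and planted
target recovery, on a reduced number of instances for a quick look.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "scripts"))

from acceptance import (  # noqa: E402
    knockout_agreement,
    lp_bfs_agreement,
    planted_recovery,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    seed = 7
    summary = {}
    value, n = lp_bfs_agreement(seed, n_toys=50)
    summary["lp_bfs_distance_agreement_pct"] = {"value": value, "n": n}
    print(f"LP vs BFS distance agreement: {value:.1f}% ({n} pairs)")
    value, n = knockout_agreement(seed, n_toys=50)
    summary["knockout_oracle_agreement_pct"] = {"value": value, "n": n}
    print(f"knockout vs exhaustive re-solve agreement: {value:.1f}% ({n} genes)")
    value, n = planted_recovery(seed, seeds_per_distance=5)
    summary["planted_target_recovery_pct"] = {"value": value, "n": n}
    print(f"planted-target recovery: {value:.1f}% ({n} pipelines)")
    out = ROOT / "oracle_benchmarks.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(summary, indent=1) + "\n")
    print(f"summary written to {out}")


if __name__ == "__main__":
    main()
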