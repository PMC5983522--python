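#!/usr/bin/env python
"""Directional overlap significance at the published study counts.

The four integers of the Brassica tuber study — r = 841 direction-
concordant shared DEGs, k1 = 3709 and k2 = 6521 DEGs, N = 38192 testable
loci — are enough to re-derive its headline statistic; no files needed.
Writes results/headline_overlap.json.
"""

import json
from pathlib import Path

from coredeg.io import write_results
from coredeg.overlap import directional_overlap_test, nondirectional_overlap_test

R, K1, K2, N = 841, 3709, 6521, 38192


def main() -> None:
    directional = directional_overlap_test(R, K1, K2, N)
    nondirectional = nondirectional_overlap_test(R, K1, K2, N)
    out = Path("results/headline_overlap.json")
    write_results(
        {"directional": directional.to_dict(),
         "nondirectional": nondirectional.to_dict()},
        out, format="json")
    print(f"directional (2N): p = {directional.p_value:.2e}, "
          f"expected r = {directional.expected_r:.2f}, "
          f"fold = {directional.fold_enrichment:.2f}")
    print(f"non-directional (N): log10 p = {nondirectional.log10_p:.1f}")
    print(json.dumps({"out": str(out)}))


if __name__ == "__main__":
    main()
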