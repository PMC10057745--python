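#!/usr/bin/env python
"""Fit the within-group truncated-GEV size-biomass distributions.

For every group, match the truncated distribution's 0.05th/50th/99.95th
percentiles to the reported minimum/median/maximum body size, with the
base truncation window (2 decades below the minimum, none above the
maximum). Writes the fitted parameters and fit residuals to
results/group_fits.json.
"""

import json
from pathlib import Path

from sizespectra.bootstrap import initial_fits
from sizespectra.catalog import load_base_catalog
from sizespectra.gev import FitConfig

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    catalog = load_base_catalog()
    fits = initial_fits(catalog, FitConfig())
    rows = []
    for g, fit in zip(catalog, fits):
        rows.append({"group": g.name, "realm": g.realm, "ssq": fit.ssq,
                     **fit.dist.to_dict()})
        print(
            f"{g.name:32s} mu={fit.dist.mu:8.2f} sigma={fit.dist.sigma:7.2f} "
            f"xi={fit.dist.xi:6.2f}  ssq={fit.ssq:.2e}"
        )
    OUT.mkdir(exist_ok=True)
    (OUT / "group_fits.json").write_text(json.dumps(rows, indent=2))
    worst = max(rows, key=lambda r: r["ssq"])
    print(
        f"-> all 36 groups fitted; largest residual sum of squares "
        f"{worst['ssq']:.1e} ({worst['group']})."
    )


if __name__ == "__main__":
    main()
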