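#!/usr/bin/env python
"""Download the study's deposited datasets (network required; optional).

The full-scale results — the trisomic Tc1 significant-gene count, the
silent-set enrichment score on the complete 45,102-probeset ranking,
and the 2DGE differential-protein count — need the original deposited
data, which this repository does not ship.  This helper fetches them so
the pipeline can be rerun at full scale:

  GEO GSE19836            120 overexpression arrays (induced/uninduced,
                          20 genes x 3 clones)
  ArrayExpress E-MEXP-654 trisomic Tc1 vs control ES-cell arrays
  World-2DPAGE 0021       Runx1 2DGE spot volumes

Nothing in the package or test suite imports this module.
"""

from __future__ import annotations

import argparse
import urllib.request
from pathlib import Path

SOURCES = {
    "GSE19836_series_matrix.txt.gz": (
        "https://ftp.ncbi.nlm.nih.gov/geo/series/GSE19nnn/GSE19836/matrix/"
        "GSE19836_series_matrix.txt.gz"
    ),
    "E-MEXP-654.processed.zip": (
        "https://www.ebi.ac.uk/biostudies/files/E-MEXP-654/"
        "E-MEXP-654.processed.1.zip"
    ),
}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("reference_data"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    for name, url in SOURCES.items():
        dest = args.out / name
        if dest.exists():
            print(f"{name}: already present")
            continue
        print(f"fetching {url}")
        urllib.request.urlretrieve(url, dest)
    print(
        "note: the World-2DPAGE spot table (accession 0021) must be "
        "exported manually from the ExPASy 2D-PAGE portal"
    )


if __name__ == "__main__":
    main()
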