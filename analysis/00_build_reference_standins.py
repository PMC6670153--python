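#!/usr/bin/env python
"""Regenerate the synthetic stand-in reference tables shipped with the package.

The per-cell-type presence matrices, the region coordinate table, the EST
catalog and the transcript set under ``src/intronprom/data`` are fully
deterministic (fixed build seed inside the package); this script rewrites
them in place and is a no-op when nothing changed.
"""

from pathlib import Path

from intronprom.standins import build_standin_tables

if __name__ == "__main__":
    outdir = Path(__file__).resolve().parents[1] / "src" / "intronprom" / "data"
    build_standin_tables(outdir)
    print(f"stand-in tables written to {outdir}")
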