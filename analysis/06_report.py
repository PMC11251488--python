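#!/usr/bin/env python
"""Render the human-readable summary of the analysis run directory."""

from pathlib import Path

from hdprog import pipeline

RUN = Path(__file__).resolve().parents[1] / "results" / "run"

if __name__ == "__main__":
    text = pipeline.report(RUN)
    (RUN / "report.txt").write_text(text)
    print(text)
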