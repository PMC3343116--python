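#!/usr/bin/env python
"""Run the scripted model calibration and write the packaged parameter set.

Usage: python scripts/calibrate.py [--out src/pfcpersist/data/calibrated.yaml]
"""
import argparse
from pathlib import Path

from pfcpersist.calibrate import calibrate

if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path,
                    default=Path("src/pfcpersist/data/calibrated.yaml"))
    args = ap.parse_args()
    calibrate(verbose=True, out_path=args.out)
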