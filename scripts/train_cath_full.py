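#!/usr/bin/env python
"""Full-scale training on a local copy of the CATH non-redundant domain set.

This is the out-of-desk-scale protocol: it expects the released domain set
(tens of thousands of PDB-format files) on local disk and a long CPU/GPU
budget, and is NOT exercised by the test suite.  Desk-scale smoke training
goes through ``torsiondiff train`` with reduced settings instead.

Protocol: chains shorter than 40 residues are excluded; longer chains are
re-cropped to a random 128-residue window each epoch; angles are normalized
by their training-set circular mean; the denoiser (embed dim 384, 12
layers) trains with AdamW, peak learning rate 5e-5 with linear warmup over
the first 10% of epochs and linear decay to zero, selecting the
best-validation-loss checkpoint.

Example:
    python scripts/train_cath_full.py --data-dir /data/cath --out runs/full
"""

import argparse
import sys


def main() -> None:
    parser = argparse.ArgumentParser(
        description=__doc__, formatter_class=argparse.RawDescriptionHelpFormatter)
    parser.add_argument("--data-dir", required=True,
                        help="Directory of PDB-format domain files.")
    parser.add_argument("--out", required=True, help="Run output directory.")
    parser.add_argument("--epochs", type=int, default=10_000)
    parser.add_argument("--batch-size", type=int, default=512)
    parser.add_argument("--timesteps", type=int, default=1000)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    from torsiondiff.cli import train

    train.callback(
        data_dir=args.data_dir, outdir=args.out, epochs=args.epochs,
        batch_size=args.batch_size, timesteps=args.timesteps,
        embed_dim=384, depth=12, heads=6, max_length=128,
        peak_lr=5e-5, seed=args.seed, resume_dir=None)


if __name__ == "__main__":
    sys.exit(main())
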