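"""Pseudo-bulk differential expression for every PT identity.

Counts are summed per mouse within each identity; an NB Wald GLM with design
~ sex + genotype (log size-factor offset) is fit for the four isoform
contrasts at the late timepoint (VKO vs ConKO, VHKO/VEKO/VHEKO vs VKO) and
the three temporal contrasts (VKO vs ConKO early; late vs early within VKO
and within ConKO).  Writes one TSV per identity x contrast.
"""

import argparse
from pathlib import Path

from hifsort.de import call_regulated
from hifsort.io import read_matrix
from hifsort.pipeline import PipelineConfig, de_all_contrasts, viable_identities

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--indir", type=Path, default=ROOT / "results" / "annotated")
    ap.add_argument("--outdir", type=Path, default=ROOT / "results" / "de")
    args = ap.parse_args()

    adata = read_matrix(
        args.indir / "matrix.mtx", args.indir / "genes.tsv", args.indir / "metadata.tsv"
    )
    cfg = PipelineConfig()
    identities = viable_identities(adata)
    print(f"identities with full replicate structure: {identities}")
    tables = de_all_contrasts(adata, identities, cfg)

    args.outdir.mkdir(parents=True, exist_ok=True)
    for identity, de_tables in tables.items():
        for label, de in de_tables.items():
            de.assign(gene=de.index).to_csv(
                args.outdir / f"{identity}__{label}.tsv", sep="\t", index=False
            )
        up, down = call_regulated(de_tables["VKO_vs_ConKO_late"])
        print(f"{identity}: VKO vs ConKO (late) {len(up)} up / {len(down)} down "
              f"regulated genes")
    print(f"DE tables written to {args.outdir}")


if __name__ == "__main__":
    main()
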