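"""GFF3 input/output for gene models.

Only ``gene`` features are consumed; coordinates are converted between GFF3's
1-based inclusive convention and the package-internal 0-based half-open one
at this boundary.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import gffutils

from .synteny import GeneModel

__all__ = ["read_gene_models", "write_gene_models"]


def read_gene_models(path: str | Path, species: str) -> list[GeneModel]:
    """Load gene features from a GFF3 file as (unranked) gene models.

    The feature ``ID`` attribute is the locus ID; features without an ID are
    rejected.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    models = []
    for feat in db.features_of_type("gene"):
        ids = feat.attributes.get("ID")
        if not ids:
            raise ValueError(f"{path}: gene feature without ID at {feat.seqid}:{feat.start}")
        models.append(
            GeneModel(
                locus_id=ids[0],
                species=species,
                chromosome=feat.seqid,
                start=feat.start - 1,  # 1-based inclusive -> 0-based half-open
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
            )
        )
    return models


def write_gene_models(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as a minimal GFF3 file (gene features only)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda g: (g.chromosome, g.start, g.locus_id)):
            fh.write(
                "\t".join(
                    (
                        m.chromosome,
                        "locustrans",
                        "gene",
                        str(m.start + 1),
                        str(m.end),
                        ".",
                        m.strand,
                        ".",
                        f"ID={m.locus_id};Name={m.locus_id}",
                    )
                )
                + "\n"
            )
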