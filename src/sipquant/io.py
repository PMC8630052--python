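"""Readers and writers for the plain-text and image formats the pipeline
consumes: tab-delimited peak lists and identification tables, per-bin
protein FASTA, multi-page TIFF ion-image stacks, and 16-bit label masks.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO

from .attribution import ProteinBin
from .nanosims import CellROI, IonImageStack
from .proteinsip import ObservedSpectrum, PeptideIdentification

__all__ = [
    "read_peak_list",
    "write_peak_list",
    "read_identifications",
    "write_identifications",
    "read_bins_fasta",
    "write_bins_fasta",
    "read_stack_tiff",
    "write_stack_tiff",
    "read_label_mask",
    "write_label_mask",
]


def read_peak_list(path: str | Path) -> ObservedSpectrum:
    """Read a tab-delimited (mz, intensity) peak list.

    Lines starting with '#' and a header line beginning with 'mz' are
    skipped. Malformed lines raise with the file name and line number.
    """
    path = Path(path)
    mz, inten = [], []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("mz"):
                continue
            parts = line.split("\t")
            try:
                mz.append(float(parts[0]))
                inten.append(float(parts[1]))
            except (IndexError, ValueError):
                raise ValueError(
                    f"{path}:{lineno}: expected 'mz<TAB>intensity', got {line!r}"
                ) from None
    return ObservedSpectrum(mz=np.array(mz), intensity=np.array(inten))


def write_peak_list(spec: ObservedSpectrum, path: str | Path) -> None:
    df = pd.DataFrame({"mz": spec.mz, "intensity": spec.intensity})
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_identifications(path: str | Path) -> list[PeptideIdentification]:
    """Read a tab-delimited identification table with columns
    sequence, charge, sample, protein_ids (';'-separated, may be empty)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sequence", "charge", "sample"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        prot = tuple(p for p in row.get("protein_ids", "").split(";") if p)
        out.append(
            PeptideIdentification(
                sequence=row["sequence"],
                charge=int(row["charge"]),
                sample=row["sample"],
                protein_ids=prot,
            )
        )
    return out


def write_identifications(ids: list[PeptideIdentification], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sequence": [i.sequence for i in ids],
            "charge": [i.charge for i in ids],
            "sample": [i.sample for i in ids],
            "protein_ids": [";".join(i.protein_ids) for i in ids],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_bins_fasta(paths: dict[str, str | Path]) -> list[ProteinBin]:
    """Read one protein FASTA per bin; ``paths`` maps bin id → file."""
    bins = []
    for bin_id in sorted(paths):
        pbin = ProteinBin(bin_id=bin_id)
        for record in SeqIO.parse(str(paths[bin_id]), "fasta"):
            pbin.add(record.id, str(record.seq))
        if not pbin.proteins:
            raise ValueError(f"bin {bin_id}: no sequences in {paths[bin_id]}")
        bins.append(pbin)
    return bins


def write_bins_fasta(bins: list[ProteinBin], out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for pbin in bins:
        path = out_dir / f"{pbin.bin_id}.faa"
        with path.open("w") as fh:
            for pid in sorted(pbin.proteins):
                fh.write(f">{pid}\n{pbin.proteins[pid]}\n")
        paths[pbin.bin_id] = path
    return paths


def write_stack_tiff(stack: IonImageStack, path: str | Path) -> None:
    """Write a (scan, species, row, col) stack as multi-page TIFF with the
    species labels and pixel size in the image description."""
    meta = {"species": list(stack.species), "pixel_size_um": stack.pixel_size_um}
    tifffile.imwrite(
        str(path),
        stack.counts.astype(np.int32),
        description=json.dumps(meta),
    )


def read_stack_tiff(path: str | Path) -> IonImageStack:
    with tifffile.TiffFile(str(path)) as tf:
        counts = tf.asarray()
        desc = tf.pages[0].description
    meta = json.loads(desc)
    return IonImageStack(
        counts=counts,
        species=tuple(meta["species"]),
        pixel_size_um=float(meta["pixel_size_um"]),
    )


def write_label_mask(rois: list[CellROI], shape: tuple[int, int], path: str | Path) -> None:
    mask = np.zeros(shape, dtype=np.uint16)
    for roi in rois:
        mask[roi.rows, roi.cols] = roi.label
    tifffile.imwrite(str(path), mask)


def read_label_mask(path: str | Path) -> list[CellROI]:
    """Read an externally drawn 16-bit label image into ROIs (mask-import
    path for parity with manually defined regions)."""
    mask = tifffile.imread(str(path))
    rois = []
    for lab in np.unique(mask):
        if lab == 0:
            continue
        rr, cc = np.nonzero(mask == lab)
        rois.append(CellROI(label=int(lab), rows=rr, cols=cc))
    return rois
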