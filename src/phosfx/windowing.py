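"""Fixed-length, pad-marked residue windows around candidate phosphosites.

A site window covers 15 residues upstream and 15 downstream of the target
S/T/Y residue (31 positions total by default); positions that fall outside
the sequence are filled with the '*' pad symbol, whose embedding row is
all zeros, and flagged 0 in the binary mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embedding import pad_vector
from .types import PAD_SYMBOL, STY, EmbeddingMatrix, ProteinRecord

DEFAULT_HALF_WIDTH = 15  # -> window length 31


@dataclass(frozen=True)
class SiteWindow:
    """A (2w+1)-long window centred on a 1-based sequence position.

    ``mask[i]`` is 1 where ``window_seq[i]`` is a real residue and 0 where
    it is the '*' pad; ``window_emb`` (attached separately) has zero rows
    exactly at pad slots.
    """

    protein_id: str
    position: int  # 1-based centre
    window_seq: str
    mask: np.ndarray
    window_emb: np.ndarray | None = None

    @property
    def half_width(self) -> int:
        return (len(self.window_seq) - 1) // 2

    @property
    def center_residue(self) -> str:
        return self.window_seq[self.half_width]


def extract_window(
    protein: ProteinRecord,
    position: int,
    half_width: int = DEFAULT_HALF_WIDTH,
    require_sty: bool = True,
) -> SiteWindow:
    """Cut the residue window [position-w, position+w] with '*' padding.

    ``require_sty`` enforces that the centre is a phosphorylatable residue
    (S, T or Y); relax it for exploratory use on arbitrary positions.
    """
    L = len(protein.sequence)
    if not 1 <= position <= L:
        raise ValueError(
            f"position {position} out of bounds for {protein.id!r} (L={L})"
        )
    centre = protein.residue(position)
    if require_sty and centre not in STY:
        raise ValueError(
            f"{protein.id}:{position} is {centre!r}, not a phosphorylatable S/T/Y"
        )
    w = int(half_width)
    chars: list[str] = []
    mask = np.zeros(2 * w + 1, dtype=np.int8)
    for offset in range(-w, w + 1):
        pos = position + offset
        if 1 <= pos <= L:
            chars.append(protein.sequence[pos - 1])
            mask[offset + w] = 1
        else:
            chars.append(PAD_SYMBOL)
    return SiteWindow(
        protein_id=protein.id, position=position, window_seq="".join(chars), mask=mask
    )


def export_windows_tsv(windows, path) -> None:
    """Write windows as TSV (protein_id, position, window_seq) for inspection."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_id\tposition\twindow_seq\n")
        for w in windows:
            fh.write(f"{w.protein_id}\t{w.position}\t{w.window_seq}\n")


def window_embedding(window: SiteWindow, emb: EmbeddingMatrix) -> SiteWindow:
    """Attach embedding rows to a window, cut from the full-sequence matrix.

    Real slots copy the matching rows of ``emb``; pad slots get the zero
    pad vector. The window must come from the same protein, and every real
    position must be covered by the (possibly truncated) embedding.
    """
    if emb.protein_id != window.protein_id:
        raise ValueError(
            f"window is from {window.protein_id!r} but embedding is for "
            f"{emb.protein_id!r}"
        )
    w = window.half_width
    max_real = window.position + int(np.max(np.nonzero(window.mask)[0])) - w
    if max_real > emb.length:
        raise ValueError(
            f"site {window.protein_id}:{window.position}: window reaches "
            f"position {max_real} but the embedding only covers "
            f"{emb.length} residues (truncated?)"
        )
    rows = np.empty((2 * w + 1, emb.dim), dtype=np.float64)
    pad = pad_vector(emb.dim)
    for i in range(2 * w + 1):
        pos = window.position + (i - w)
        rows[i] = emb.values[pos - 1] if window.mask[i] else pad
    return SiteWindow(
        protein_id=window.protein_id,
        position=window.position,
        window_seq=window.window_seq,
        mask=window.mask,
        window_emb=rows,
    )
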