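"""Allometric size correction of morphometric characters.

Linear measurements scale with body size, so raw among-specimen variation
mixes shape differences with growth.  The classical remedy is the
allometric adjustment

    X_adj = log10(X) - beta * (log10(SVL) - mean log10(SVL)),

which standardises every character to the value expected at a common
reference body size.  ``beta`` is the allometric slope of log10(X) on
log10(SVL); in the multispecies (pooled) variant it is estimated from
group-mean-centred data so that among-OTU shape differences do not leak
into the slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MorphoDataset

__all__ = ["CorrectedMatrix", "thorpe_correct", "corrected_dataset"]

MODES = ("pooled", "per-otu", "none")


@dataclass
class CorrectedMatrix:
    """Size-adjusted, log10-scale character values plus the fit metadata."""

    values: np.ndarray            # (n, d) adjusted log10 values
    slopes: np.ndarray            # (d,) pooled slopes, or (g, d) per-OTU slopes
    reference_log_size: float     # grand mean of log10 body size
    mode: str
    character_names: list[str]


def _group_centred(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    out = np.empty_like(values)
    for g in np.unique(labels):
        mask = labels == g
        out[mask] = values[mask] - values[mask].mean(axis=0)
    return out


def thorpe_correct(ds: MorphoDataset, mode: str = "pooled") -> CorrectedMatrix:
    """Remove body-size-related variation from every character.

    Parameters
    ----------
    ds
        Raw (strictly positive) measurements.
    mode
        ``"pooled"`` estimates one common slope per character from
        group-mean-centred log data (the standard multispecies variant);
        ``"per-otu"`` estimates a separate slope within every OTU;
        ``"none"`` log10-transforms without any slope adjustment.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if ds.log_scale:
        raise ValueError("dataset is already on log scale / corrected; refusing to correct twice")
    labels = ds.otu_labels.astype(str)
    log_size = np.log10(ds.body_size)
    log_chars = np.log10(ds.characters)
    ref = float(log_size.mean())
    names = list(ds.character_names)

    if mode == "none":
        return CorrectedMatrix(log_chars.copy(), np.zeros(ds.n_characters), ref, mode, names)

    if mode == "pooled":
        cs = _group_centred(log_size[:, None], labels)[:, 0]
        cx = _group_centred(log_chars, labels)
        ssx = float(cs @ cs)
        if ssx <= 0:
            raise ValueError(
                "body size is constant within every OTU; the allometric slope is "
                "undefined — use mode='none'"
            )
        beta = cs @ cx / ssx                                # (d,)
        adjusted = log_chars - np.outer(log_size - ref, beta)
        return CorrectedMatrix(adjusted, beta, ref, mode, names)

    # per-otu: a separate slope within each OTU, same grand-mean reference
    otus = sorted(np.unique(labels))
    slopes = np.empty((len(otus), ds.n_characters))
    adjusted = np.empty_like(log_chars)
    for i, otu in enumerate(otus):
        mask = labels == otu
        if mask.sum() < 2:
            raise ValueError(f"OTU {otu!r} has < 2 specimens; per-OTU slope is undefined")
        s = log_size[mask] - log_size[mask].mean()
        ssx = float(s @ s)
        if ssx <= 0:
            raise ValueError(
                f"OTU {otu!r} has constant body size; per-OTU slope is undefined — use mode='none'"
            )
        beta = s @ (log_chars[mask] - log_chars[mask].mean(axis=0)) / ssx
        slopes[i] = beta
        adjusted[mask] = log_chars[mask] - np.outer(log_size[mask] - ref, beta)
    return CorrectedMatrix(adjusted, slopes, ref, "per-otu", names)


def corrected_dataset(ds: MorphoDataset, mode: str = "pooled", *,
                      keep_body_size: bool = False) -> MorphoDataset:
    """Apply :func:`thorpe_correct` and repackage the result as a dataset.

    The returned object carries ``log_scale=True`` so a second correction is
    refused.  The body-size column is dropped by default; with
    ``keep_body_size`` it is carried through as log10(SVL) (stored in the
    body-size slot).
    """
    corr = thorpe_correct(ds, mode)
    if keep_body_size:
        characters = np.column_stack([np.log10(ds.body_size), corr.values])
        names = [f"log10_{ds.body_size_name}"] + list(ds.character_names)
    else:
        characters = corr.values
        names = list(ds.character_names)
    return MorphoDataset(
        specimen_ids=list(ds.specimen_ids),
        otu_labels=ds.otu_labels.copy(),
        body_size=np.log10(ds.body_size),
        characters=characters,
        character_names=names,
        body_size_name=f"log10_{ds.body_size_name}",
        log_scale=True,
    )
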