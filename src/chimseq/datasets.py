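"""Packaged validation data from the clinical series the assay was
developed on: 14 MDS patients who received allogeneic HSCT, with paired
STR/NGS donor-chimerism measurements on 25 post-transplant samples (one
NGS value unavailable), per-sample mutant allele burdens of each
patient's tracked mutations, and the published per-marker blank
statistics (mean %BE and SD over mutation-negative samples) from which
the limit-of-blank thresholds derive.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .concordance import PairedChimerism, load_pairs
from .io_counts import GenomicLocus, MutationMarker
from .mrd import LOB_SD_MULTIPLIER, LoB


def _data_path(name: str):
    return resources.files("chimseq.data").joinpath(name)


def load_study_pairs() -> list[PairedChimerism]:
    """The evaluable paired STR (reference) / NGS (test) chimerism
    percentages; the sample missing its NGS value is excluded listwise."""
    with resources.as_file(_data_path("study_chimerism_pairs.tsv")) as p:
        return load_pairs(p)


def load_study_pairs_frame() -> pd.DataFrame:
    """The raw pairs table (including the NA row and patient/group labels)."""
    with resources.as_file(_data_path("study_chimerism_pairs.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_study_mab() -> pd.DataFrame:
    """Per-sample mutant allele burdens of each patient's tracked mutations."""
    with resources.as_file(_data_path("study_mab.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_study_lob_frame() -> pd.DataFrame:
    with resources.as_file(_data_path("study_lob.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def study_mutation_markers() -> list[MutationMarker]:
    df = load_study_lob_frame()
    return [
        MutationMarker(
            locus=GenomicLocus(row["chrom"], int(row["pos"])),
            ref=row["ref"],
            mut=row["mut"],
            label=row["label"],
        )
        for _, row in df.iterrows()
    ]


def study_lob_thresholds(k: float = LOB_SD_MULTIPLIER) -> dict[str, LoB]:
    """Limit-of-blank per tracked mutation, recomputed as mean + k·SD from
    the packaged blank statistics."""
    df = load_study_lob_frame()
    out = {}
    for _, row in df.iterrows():
        mean, sd = float(row["pct_be"]), float(row["pct_sd"])
        out[row["label"]] = LoB(
            label=row["label"], mean_be=mean, sd_be=sd,
            lob=mean + k * sd, n_blanks=0,
        )
    return out
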