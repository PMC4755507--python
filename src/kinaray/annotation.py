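"""Kinase-substrate annotation: peptide sequences and phospho-sites.

The package ships the eleven differential kinase-substrate pairs reported
for the Treg-vs-Teff contrast (kinase, substrate protein, 11-mer peptide,
phosphorylated residue) as its default annotation fixture; user-supplied
annotation tables use the same TSV columns.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

REQUIRED_COLUMNS = ["substrate_id", "kinase", "substrate", "peptide", "site"]
PHOSPHO_RESIDUES = {"S", "T", "Y"}


def load_annotation(path=None, validate: bool = True) -> pd.DataFrame:
    """Load a substrate annotation table (TSV).

    With no ``path``, returns the bundled 11-row differential-kinase
    table.  Validation enforces 11-mer peptides and a phospho-site
    residue in {S, T, Y}.
    """
    if path is None:
        ref = resources.files("kinaray.data") / "table1_substrates.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation lacks columns: {missing}")
    if validate:
        bad_pep = df[df["peptide"].str.len() != 11]
        if not bad_pep.empty:
            raise ValueError(
                f"peptides must be 11-mers: {list(bad_pep['peptide'])}"
            )
        residues = df["site"].str[0]
        bad_site = df[~residues.isin(PHOSPHO_RESIDUES)]
        if not bad_site.empty:
            raise ValueError(
                f"phospho-site residue must be S/T/Y: {list(bad_site['site'])}"
            )
    return df
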