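"""The packaged glioma proto-oncogene set.

29 gene symbols implicated in gliomagenesis: 23 drawn from the COSMIC
Cancer Gene Census entries with a known role in glioma (including
glioblastoma, astrocytoma and oligodendroglioma), plus six genes listed
there under other tumour types but independently implicated in glioma —
KRAS, MYC, CDKN2A(p16), CDKN2A(p14), CTNNB1(beta-catenin) and ERBB2(HER2).

The packaged file ``data/oncogene_set_synthetic.csv`` is a synthetic
stand-in: the six additions are fixed by the model definition, while the 23
glioma-census symbols are a curated reconstruction from the public COSMIC
census (the original supplementary listing is not redistributed here).
The set's size (29) is what enters the model as ``n_onco``; the identity of
the symbols does not affect any computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = ["OncogeneSet", "load_oncogene_set", "EXPECTED_SIZE", "EXPECTED_ADDITIONS"]

EXPECTED_SIZE = 29
EXPECTED_ADDITIONS = frozenset(
    {
        "KRAS",
        "MYC",
        "CDKN2A(p16)",
        "CDKN2A(p14)",
        "CTNNB1(beta-catenin)",
        "ERBB2(HER2)",
    }
)
_VALID_SOURCES = {"cosmic-glioma", "other-tumour-types-addition"}


class OncogeneSetIntegrityError(ValueError):
    """The packaged oncogene fixture violates its invariants."""


@dataclass(frozen=True)
class OncogeneSet:
    """The glioma proto-oncogene symbols with their provenance tags."""

    symbols: tuple
    sources: tuple

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def additions(self) -> frozenset:
        """The six symbols added from COSMIC's other-tumour-type entries."""
        return frozenset(
            s for s, tag in zip(self.symbols, self.sources)
            if tag == "other-tumour-types-addition"
        )

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols


def _validate(df: pd.DataFrame) -> OncogeneSet:
    if list(df.columns) != ["symbol", "source"]:
        raise OncogeneSetIntegrityError(
            f"oncogene fixture must have columns ['symbol', 'source'], got {list(df.columns)}"
        )
    symbols = [str(s).strip() for s in df["symbol"]]
    sources = [str(s).strip() for s in df["source"]]
    if len(symbols) != len(set(symbols)):
        dupes = sorted({s for s in symbols if symbols.count(s) > 1})
        raise OncogeneSetIntegrityError(f"duplicate gene symbols in fixture: {dupes}")
    if len(symbols) != EXPECTED_SIZE:
        raise OncogeneSetIntegrityError(
            f"oncogene fixture must contain exactly {EXPECTED_SIZE} genes, got {len(symbols)}"
        )
    bad = sorted(set(sources) - _VALID_SOURCES)
    if bad:
        raise OncogeneSetIntegrityError(f"unknown source tags: {bad}")
    oset = OncogeneSet(symbols=tuple(symbols), sources=tuple(sources))
    if oset.additions != EXPECTED_ADDITIONS:
        raise OncogeneSetIntegrityError(
            f"the other-tumour-type additions must be exactly "
            f"{sorted(EXPECTED_ADDITIONS)}, got {sorted(oset.additions)}"
        )
    return oset


def load_oncogene_set(path=None) -> OncogeneSet:
    """Load and validate the 29-gene set (packaged fixture by default).

    ``path`` overrides the packaged file, mainly for integrity testing.
    Raises :class:`OncogeneSetIntegrityError` if the set is malformed.
    """
    if path is None:
        ref = resources.files("nscglioma").joinpath("data/oncogene_set_synthetic.csv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, dtype=str)
    else:
        df = pd.read_csv(path, dtype=str)
    return _validate(df)
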