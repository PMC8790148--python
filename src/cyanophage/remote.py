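"""Minimal helper to fetch a nucleotide FASTA by accession from NCBI e-utils.

Used only for composition checks against deposited records; everything
else in the toolkit is offline. Requires network access.
"""

from __future__ import annotations

import urllib.parse
import urllib.request

from .errors import FormatError
from .seq_core import SeqRecord

EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"


def fetch_genome(accession: str, timeout: float = 30.0) -> SeqRecord:
    """Download one nucleotide record as FASTA and return it parsed."""
    query = urllib.parse.urlencode(
        {"db": "nuccore", "id": accession, "rettype": "fasta", "retmode": "text"}
    )
    with urllib.request.urlopen(f"{EUTILS}?{query}", timeout=timeout) as resp:
        text = resp.read().decode()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith(">"):
        raise FormatError(f"unexpected e-utils response for {accession!r}")
    header = lines[0][1:]
    name, _, desc = header.partition(" ")
    seq = "".join(lines[1:]).upper()
    return SeqRecord(id=name, seq=seq, description=desc)
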