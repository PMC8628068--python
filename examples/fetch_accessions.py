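"""Download the five published plasmid GenBank records (network required).

Fetches the plasmid sequences from NCBI into data/accessions/ so the
published-plasmid feature checks can run; the records are too large to
ship with the package.  Run once with internet access:

    python examples/fetch_accessions.py
"""

import urllib.request
from pathlib import Path

ACCESSIONS = ["KR827392.1", "KF745070.2", "MT720903", "MT441554", "MT720906"]
URL = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&rettype=gbwithparts&retmode=text&id={acc}"
)

outdir = Path(__file__).resolve().parent.parent / "data" / "accessions"
outdir.mkdir(parents=True, exist_ok=True)

for acc in ACCESSIONS:
    dest = outdir / f"{acc}.gb"
    if dest.exists():
        print(f"{acc}: already present")
        continue
    print(f"fetching {acc} ...")
    with urllib.request.urlopen(URL.format(acc=acc), timeout=60) as resp:
        dest.write_bytes(resp.read())
    print(f"  -> {dest} ({dest.stat().st_size} bytes)")
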