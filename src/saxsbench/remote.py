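"""Opt-in fetching of deposited profiles and structures (network required).

Everything else in the package runs offline; these helpers exist only for
benchmark runs against deposited consensus data (SASBDB accessions) and
crystal structures (PDB codes).  Downloads are cached in a local directory.
"""

from __future__ import annotations

import urllib.request
from pathlib import Path

from .sas_io import AtomicModel, SASProfile, read_profile, read_structure

SASBDB_URLS = (
    "https://www.sasbdb.org/media/intensities_files/{code}.dat",
    "https://www.sasbdb.org/media/upload_final_composite_data/{code}.dat",
)
PDB_URL = "https://files.rcsb.org/download/{code}.pdb"


def _download(url: str, dest: Path, timeout: float) -> None:
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        data = resp.read()
    dest.write_bytes(data)


def fetch_sasbdb_profile(code: str, cache_dir="scratch/fetch",
                         timeout: float = 20.0) -> SASProfile:
    """Download (or reuse a cached copy of) a deposited SASBDB profile."""
    cache = Path(cache_dir)
    cache.mkdir(parents=True, exist_ok=True)
    dest = cache / f"{code}.dat"
    if not dest.exists():
        err = None
        for pattern in SASBDB_URLS:
            try:
                _download(pattern.format(code=code), dest, timeout)
                break
            except Exception as exc:    # try the next URL pattern
                err = exc
        else:
            raise ConnectionError(f"could not fetch {code}: {err}")
    return read_profile(dest, label=code, mode="consensus")


def fetch_pdb_structure(code: str, cache_dir="scratch/fetch",
                        timeout: float = 20.0) -> AtomicModel:
    """Download (or reuse a cached copy of) a PDB entry, prepared for SAXS."""
    cache = Path(cache_dir)
    cache.mkdir(parents=True, exist_ok=True)
    dest = cache / f"{code}.pdb"
    if not dest.exists():
        _download(PDB_URL.format(code=code.lower()), dest, timeout)
    return read_structure(dest)
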