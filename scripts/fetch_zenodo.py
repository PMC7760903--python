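"""Fetch the published imaging dataset and convert it to the portable format.

Downloads the deposited horse/donkey thermography dataset (Zenodo
record 4085075) and writes data/deposited/manifest.yaml plus per-animal
temperature-grid and class-map files, so that the full test suite
(including the published-statistics reproduction) can run against it.

Requires network access. The converter makes a best effort for the
layouts a deposit like this typically uses (paired NumPy ``.npy``/
``.npz`` arrays or CSV grids named per animal, one temperature grid and
one integer class map each, 240x320); if the archive's structure is not
recognised it stops and prints what it found, so the mapping can be
completed by hand with ``thermopattern.io.save_dataset``.
"""

from __future__ import annotations

import io as stdio
import json
import re
import sys
import urllib.request
import zipfile
from pathlib import Path

import numpy as np

import thermopattern as tp

RECORD_API = "https://zenodo.org/api/records/4085075"
OUT_DIR = Path(__file__).resolve().parents[1] / "data" / "deposited"


def _animal_id_from_name(name: str) -> str | None:
    match = re.search(r"([HD])[._-]?(\d+)", Path(name).stem, flags=re.IGNORECASE)
    if not match:
        return None
    return f"{match.group(1).upper()}.{int(match.group(2))}"


def _load_array(payload: bytes, name: str) -> np.ndarray:
    if name.endswith(".npy"):
        return np.load(stdio.BytesIO(payload), allow_pickle=False)
    if name.endswith(".csv") or name.endswith(".txt"):
        return np.loadtxt(stdio.BytesIO(payload), delimiter=",")
    raise ValueError(f"unsupported array file: {name}")


def main() -> None:
    with urllib.request.urlopen(RECORD_API, timeout=60) as response:
        record = json.load(response)
    files = record.get("files", [])
    print(f"record has {len(files)} files:")
    for entry in files:
        print(f"  {entry.get('key')} ({entry.get('size', '?')} bytes)")

    grids: dict[str, dict[str, np.ndarray]] = {}
    for entry in files:
        url = entry["links"]["self"]
        name = entry["key"]
        with urllib.request.urlopen(url, timeout=600) as response:
            payload = response.read()
        members: list[tuple[str, bytes]]
        if name.endswith(".zip"):
            archive = zipfile.ZipFile(stdio.BytesIO(payload))
            members = [(m, archive.read(m)) for m in archive.namelist() if not m.endswith("/")]
        else:
            members = [(name, payload)]
        for member_name, data in members:
            animal_id = _animal_id_from_name(member_name)
            if animal_id is None:
                continue
            try:
                array = _load_array(data, member_name)
            except ValueError:
                continue
            kind = "class_map" if re.search(r"class|map|label|annot", member_name, re.I) else "image"
            grids.setdefault(animal_id, {})[kind] = array

    records = []
    for animal_id, parts in sorted(grids.items()):
        if "image" not in parts or "class_map" not in parts:
            print(f"incomplete pair for {animal_id}: {sorted(parts)}; skipping")
            continue
        species = "horse" if animal_id.startswith("H") else "donkey"
        excluded = animal_id in ("D.17", "D.18")
        records.append(
            tp.AnimalRecord(
                tp.AnimalMetadata(animal_id=animal_id, species=species, excluded=excluded),
                tp.ThermalImage(np.asarray(parts["image"], dtype=float)),
                tp.ClassMap(np.asarray(parts["class_map"]).astype(int)),
            )
        )
    if not records:
        sys.exit(
            "No recognisable image/class-map pairs found; inspect the listing "
            "above and convert manually with thermopattern.io.save_dataset."
        )
    manifest = tp.save_dataset(tp.Dataset(records=records), OUT_DIR)
    print(f"wrote {len(records)} records -> {manifest}")


if __name__ == "__main__":
    main()
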