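"""Access to packaged literature reference tables.

These are published values from the original red-algal plastid screen
(count matrices for *Palmaria* sp. (Japan) and *P. palmata*, the
photosystem sub-tables, database class counts and printed densities).
They are shipped for arithmetic reproduction, consistency checks and
comparisons only — the package never emits them as computed results.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources


@lru_cache(maxsize=1)
def published_screen_counts() -> dict:
    """The packaged reference-count bundle (see the ``_note`` key inside)."""
    ref = resources.files("pepscan.data") / "published_screen_counts.json"
    with resources.as_file(ref) as path, open(path) as fh:
        return json.load(fh)
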