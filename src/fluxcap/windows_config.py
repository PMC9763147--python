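"""Load cycle-window definitions from a small YAML file.

Schema: four keys (``discarded``, ``baseline``, ``treatment``, ``ar``),
each a list of 1-based cycle indices; omitted keys keep the defaults of
the standard 9-cycle protocol.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .errors import FormatError
from .plate import CycleWindows


def load_windows(path: str | Path) -> CycleWindows:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: windows file must be a mapping")
    unknown = set(raw) - {"discarded", "baseline", "treatment", "ar"}
    if unknown:
        raise FormatError(f"{path}: unknown window key(s) {sorted(unknown)}")
    defaults = CycleWindows()
    kwargs = {}
    for key in ("discarded", "baseline", "treatment", "ar"):
        if key in raw:
            kwargs[key] = frozenset(int(c) for c in raw[key])
        else:
            kwargs[key] = getattr(defaults, key)
    return CycleWindows(**kwargs)
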