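"""Small internal helpers."""

from __future__ import annotations

from pathlib import Path


def path_or_text(obj) -> str:
    """Return file contents if ``obj`` names an existing file, else str(obj)."""
    if isinstance(obj, Path):
        return obj.read_text()
    text = str(obj)
    if len(text) < 4096 and "\n" not in text:
        try:
            p = Path(text)
            if p.is_file():
                return p.read_text()
        except OSError:
            pass
    return text
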