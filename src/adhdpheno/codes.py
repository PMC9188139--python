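"""ICD code normalization and prefix matching.

EHR extracts mix dotted ("314.01") and dotless ("31401") ICD spellings, and
diagnosis-family rules are written as dotted prefixes ("314.", "F90.").
Normalizing both sides to a canonical dotted form makes prefix matching
invariant to the source dialect.
"""

from __future__ import annotations


def normalize_code(raw: str, code_system: str | None = None) -> str:
    """Return the canonical spelling of an ICD-9/ICD-10 code.

    Uppercases, strips whitespace, and places a single dot after the
    third character (the ICD category/subcategory boundary) whenever the
    code is longer than three characters.  Dotless extracts and dotted
    extracts therefore normalize to the same string.  Idempotent.

    Parameters
    ----------
    raw : str
        Code as found in the extract, e.g. ``"f90.0"`` or ``"3140"``.
    code_system : str, optional
        ``"ICD9"`` or ``"ICD10"``; accepted for symmetry with the event
        schema, the normalization rule is the same for both.

    Raises
    ------
    ValueError
        If ``raw`` is empty or whitespace-only.
    """
    compact = "".join(str(raw).split()).upper().replace(".", "")
    if not compact:
        raise ValueError("empty diagnosis code")
    if len(compact) > 3:
        return compact[:3] + "." + compact[3:]
    return compact


def normalize_prefix(prefix: str) -> str:
    """Normalize a code-family prefix such as ``"314."`` or ``"F90"``.

    A trailing dot (the conventional spelling for "any code in this
    family") is dropped; an internal dot is re-placed at the category
    boundary like :func:`normalize_code`.
    """
    compact = "".join(str(prefix).split()).upper()
    trailing_family = compact.endswith(".")
    compact = compact.replace(".", "")
    if not compact:
        raise ValueError("empty code prefix")
    if len(compact) > 3:
        return compact[:3] + "." + compact[3:]
    # keep <=3-char prefixes bare; "314." and "314" match the same family
    del trailing_family
    return compact


def code_matches_prefix(code: str, prefix: str) -> bool:
    """True if a (possibly raw) code belongs to the family named by *prefix*."""
    return normalize_code(code).startswith(normalize_prefix(prefix))


def code_matches_any(code: str, prefixes: list[str]) -> bool:
    norm = normalize_code(code)
    return any(norm.startswith(normalize_prefix(p)) for p in prefixes)
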