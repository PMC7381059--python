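"""Double-metaphone phonetic encoding.

Maps a name to a pronunciation code so that common misspellings and
spelling variants (SMITH/SMYTH, JON/JOHN, STEPHEN/STEVEN) share a code.
The encoder returns a primary and an alternate code; linkage keys use the
primary code only, so two names match phonetically iff their primary codes
are equal.

The implementation follows Lawrence Philips' published double-metaphone
rules. Input is expected to be an uppercase alphabetic token (the output of
name cleaning); other characters are dropped before encoding.
"""

from __future__ import annotations

_VOWELS = "AEIOUY"


def _is_slavo_germanic(word: str) -> bool:
    return "W" in word or "K" in word or "CZ" in word or "WITZ" in word


def double_metaphone(value: str, maxlength: int | None = 4) -> tuple[str, str]:
    """Return (primary, secondary) double-metaphone codes for *value*.

    Codes are truncated to ``maxlength`` characters (4 by default, matching
    the original algorithm); pass ``None`` for untruncated codes. The
    secondary code equals the primary when no alternate pronunciation rule
    fires.
    """
    word = "".join(c for c in value.upper() if ("A" <= c <= "Z") or c == " ")
    n = len(word)
    if n == 0:
        return "", ""
    last = n - 1
    pad = word + "     "
    slavo = _is_slavo_germanic(word)

    pri: list[str] = []
    sec: list[str] = []

    def add(p: str, s: str | None = None) -> None:
        if p:
            pri.append(p)
        s = p if s is None else s
        if s:
            sec.append(s)

    def ch(i: int) -> str:
        return pad[i] if 0 <= i < n else " "

    def sa(start: int, length: int, *opts: str) -> bool:
        if start < 0:
            return False
        return pad[start : start + length] in opts

    def vow(i: int) -> bool:
        return 0 <= i < n and pad[i] in _VOWELS

    pos = 0
    # silent initial clusters
    if sa(0, 2, "GN", "KN", "PN", "WR", "PS"):
        pos = 1
    if ch(0) == "X":  # e.g. Xavier
        add("S")
        pos = 1

    while pos < n:
        c = ch(pos)

        if c in _VOWELS:
            if pos == 0:
                add("A")
            pos += 1

        elif c == "B":
            add("P")
            pos += 2 if ch(pos + 1) == "B" else 1

        elif c == "C":
            # germanic -ACH-
            if (
                pos > 1
                and not vow(pos - 2)
                and sa(pos - 1, 3, "ACH")
                and ch(pos + 2) != "I"
                and (ch(pos + 2) != "E" or sa(pos - 2, 6, "BACHER", "MACHER"))
            ):
                add("K")
                pos += 2
            elif pos == 0 and sa(pos, 6, "CAESAR"):
                add("S")
                pos += 2
            elif sa(pos, 4, "CHIA"):
                add("K")
                pos += 2
            elif sa(pos, 2, "CH"):
                if pos > 0 and sa(pos, 4, "CHAE"):
                    add("K", "X")
                elif (
                    pos == 0
                    and (sa(1, 5, "HARAC", "HARIS") or sa(1, 3, "HOR", "HYM", "HIA", "HEM"))
                    and not sa(0, 5, "CHORE")
                ):
                    add("K")
                elif (
                    sa(0, 4, "VAN ", "VON ")
                    or sa(0, 3, "SCH")
                    or sa(pos - 2, 6, "ORCHES", "ARCHIT", "ORCHID")
                    or sa(pos + 2, 1, "T", "S")
                    or (
                        (sa(pos - 1, 1, "A", "O", "U", "E") or pos == 0)
                        and (
                            sa(pos + 2, 1, "L", "R", "N", "M", "B", "H", "F", "V", "W", " ")
                            or pos + 1 == last
                        )
                    )
                ):
                    add("K")
                elif pos > 0:
                    if sa(0, 2, "MC"):
                        add("K")
                    else:
                        add("X", "K")
                else:
                    add("X")
                pos += 2
            elif sa(pos, 2, "CZ") and not sa(pos - 2, 4, "WICZ"):
                add("S", "X")
                pos += 2
            elif sa(pos + 1, 3, "CIA"):
                add("X")
                pos += 3
            elif sa(pos, 2, "CC") and not (pos == 1 and ch(0) == "M"):
                if sa(pos + 2, 1, "I", "E", "H") and not sa(pos + 2, 2, "HU"):
                    if (pos == 1 and ch(pos - 1) == "A") or sa(pos - 1, 5, "UCCEE", "UCCES"):
                        add("KS")
                    else:
                        add("X")
                    pos += 3
                else:
                    add("K")
                    pos += 2
            elif sa(pos, 2, "CK", "CG", "CQ"):
                add("K")
                pos += 2
            elif sa(pos, 2, "CI", "CE", "CY"):
                if sa(pos, 3, "CIO", "CIE", "CIA"):
                    add("S", "X")
                else:
                    add("S")
                pos += 2
            else:
                add("K")
                if sa(pos + 1, 2, " C", " Q", " G"):
                    pos += 3
                elif sa(pos + 1, 1, "C", "K", "Q") and not sa(pos + 1, 2, "CE", "CI"):
                    pos += 2
                else:
                    pos += 1

        elif c == "D":
            if sa(pos, 2, "DG"):
                if sa(pos + 2, 1, "I", "E", "Y"):  # edge
                    add("J")
                    pos += 3
                else:  # Edgar
                    add("TK")
                    pos += 2
            elif sa(pos, 2, "DT", "DD"):
                add("T")
                pos += 2
            else:
                add("T")
                pos += 1

        elif c == "F":
            add("F")
            pos += 2 if ch(pos + 1) == "F" else 1

        elif c == "G":
            if ch(pos + 1) == "H":
                if pos > 0 and not vow(pos - 1):
                    add("K")
                elif pos == 0:
                    if ch(pos + 2) == "I":
                        add("J")
                    else:
                        add("K")
                elif (
                    (pos > 1 and sa(pos - 2, 1, "B", "H", "D"))
                    or (pos > 2 and sa(pos - 3, 1, "B", "H", "D"))
                    or (pos > 3 and sa(pos - 4, 1, "B", "H"))
                ):
                    pass  # Hugh, Bough: silent
                elif pos > 2 and ch(pos - 1) == "U" and sa(pos - 3, 1, "C", "G", "L", "R", "T"):
                    add("F")  # laugh, cough
                elif pos > 0 and ch(pos - 1) != "I":
                    add("K")
                pos += 2
            elif ch(pos + 1) == "N":
                if pos == 1 and vow(0) and not slavo:
                    add("KN", "N")
                elif not sa(pos + 2, 2, "EY") and ch(pos + 1) != "Y" and not slavo:
                    add("N", "KN")
                else:
                    add("KN")
                pos += 2
            elif sa(pos + 1, 2, "LI") and not slavo:  # tagliaro
                add("KL", "L")
                pos += 2
            elif pos == 0 and (
                ch(pos + 1) == "Y"
                or sa(pos + 1, 2, "ES", "EP", "EB", "EL", "EY", "IB", "IL", "IN", "IE", "EI", "ER")
            ):
                add("K", "J")
                pos += 2
            elif (
                (sa(pos + 1, 2, "ER") or ch(pos + 1) == "Y")
                and not sa(0, 6, "DANGER", "RANGER", "MANGER")
                and not sa(pos - 1, 1, "E", "I")
                and not sa(pos - 1, 3, "RGY", "OGY")
            ):
                add("K", "J")
                pos += 2
            elif sa(pos + 1, 1, "E", "I", "Y") or sa(pos - 1, 4, "AGGI", "OGGI"):
                if sa(0, 4, "VAN ", "VON ") or sa(0, 3, "SCH") or sa(pos + 1, 2, "ET"):
                    add("K")
                elif sa(pos + 1, 4, "IER "):
                    add("J")
                else:
                    add("J", "K")
                pos += 2
            else:
                add("K")
                pos += 2 if ch(pos + 1) == "G" else 1

        elif c == "H":
            if (pos == 0 or vow(pos - 1)) and vow(pos + 1):
                add("H")
                pos += 2
            else:
                pos += 1

        elif c == "J":
            if sa(pos, 4, "JOSE") or sa(0, 4, "SAN "):
                if (pos == 0 and ch(pos + 4) == " ") or sa(0, 4, "SAN "):
                    add("H")
                else:
                    add("J", "H")
                pos += 1
            else:
                if pos == 0:
                    add("J", "A")
                elif vow(pos - 1) and not slavo and (ch(pos + 1) == "A" or ch(pos + 1) == "O"):
                    add("J", "H")
                elif pos == last:
                    add("J", "")
                elif not sa(pos + 1, 1, "L", "T", "K", "S", "N", "M", "B", "Z") and not sa(
                    pos - 1, 1, "S", "K", "L"
                ):
                    add("J")
                pos += 2 if ch(pos + 1) == "J" else 1

        elif c == "K":
            add("K")
            pos += 2 if ch(pos + 1) == "K" else 1

        elif c == "L":
            if ch(pos + 1) == "L":
                # spanish -illo/-illa/-alle
                if (pos == n - 3 and sa(pos - 1, 4, "ILLO", "ILLA", "ALLE")) or (
                    (sa(last - 1, 2, "AS", "OS") or sa(last, 1, "A", "O"))
                    and sa(pos - 1, 4, "ALLE")
                ):
                    add("L", "")
                else:
                    add("L")
                pos += 2
            else:
                add("L")
                pos += 1

        elif c == "M":
            if (sa(pos - 1, 3, "UMB") and (pos + 1 == last or sa(pos + 2, 2, "ER"))) or ch(
                pos + 1
            ) == "M":
                pos += 2
            else:
                pos += 1
            add("M")

        elif c == "N":
            add("N")
            pos += 2 if ch(pos + 1) == "N" else 1

        elif c == "P":
            if ch(pos + 1) == "H":
                add("F")
                pos += 2
            else:
                add("P")
                pos += 2 if sa(pos + 1, 1, "P", "B") else 1

        elif c == "Q":
            add("K")
            pos += 2 if ch(pos + 1) == "Q" else 1

        elif c == "R":
            # french final -ier
            if (
                pos == last
                and not slavo
                and sa(pos - 2, 2, "IE")
                and not sa(pos - 4, 2, "ME", "MA")
            ):
                add("", "R")
            else:
                add("R")
            pos += 2 if ch(pos + 1) == "R" else 1

        elif c == "S":
            if sa(pos - 1, 3, "ISL", "YSL"):  # island
                pos += 1
            elif pos == 0 and sa(pos, 5, "SUGAR"):
                add("X", "S")
                pos += 1
            elif sa(pos, 2, "SH"):
                if sa(pos + 1, 4, "HEIM", "HOEK", "HOLM", "HOLZ"):
                    add("S")
                else:
                    add("X")
                pos += 2
            elif sa(pos, 3, "SIO", "SIA") or sa(pos, 4, "SIAN"):
                if not slavo:
                    add("S", "X")
                else:
                    add("S")
                pos += 3
            elif (pos == 0 and sa(pos + 1, 1, "M", "N", "L", "W")) or sa(pos + 1, 1, "Z"):
                add("S", "X")
                pos += 2 if sa(pos + 1, 1, "Z") else 1
            elif sa(pos, 2, "SC"):
                if ch(pos + 2) == "H":
                    if sa(pos + 3, 2, "OO", "ER", "EN", "UY", "ED", "EM"):
                        if sa(pos + 3, 2, "ER", "EN"):
                            add("X", "SK")
                        else:
                            add("SK")
                    else:
                        if pos == 0 and not vow(3) and ch(3) != "W":
                            add("X", "S")
                        else:
                            add("X")
                    pos += 3
                elif sa(pos + 2, 1, "I", "E", "Y"):
                    add("S")
                    pos += 3
                else:
                    add("SK")
                    pos += 3
            else:
                if pos == last and sa(pos - 2, 2, "AI", "OI"):  # french Louis
                    add("", "S")
                else:
                    add("S")
                pos += 2 if sa(pos + 1, 1, "S", "Z") else 1

        elif c == "T":
            if sa(pos, 4, "TION"):
                add("X")
                pos += 3
            elif sa(pos, 3, "TIA", "TCH"):
                add("X")
                pos += 3
            elif sa(pos, 2, "TH") or sa(pos, 3, "TTH"):
                if sa(pos + 2, 2, "OM", "AM") or sa(0, 4, "VAN ", "VON ") or sa(0, 3, "SCH"):
                    add("T")  # Thomas, Thames
                else:
                    add("0", "T")
                pos += 2
            else:
                add("T")
                pos += 2 if sa(pos + 1, 1, "T", "D") else 1

        elif c == "V":
            add("F")
            pos += 2 if ch(pos + 1) == "V" else 1

        elif c == "W":
            if sa(pos, 2, "WR"):
                add("R")
                pos += 2
            elif pos == 0 and (vow(pos + 1) or sa(pos, 2, "WH")):
                if vow(pos + 1):
                    add("A", "F")  # Wasserman / Vasserman
                else:
                    add("A")  # Wheeler
                pos += 1
            elif (
                (pos == last and vow(pos - 1))
                or sa(pos - 1, 5, "EWSKI", "EWSKY", "OWSKI", "OWSKY")
                or sa(0, 3, "SCH")
            ):
                add("", "F")
                pos += 1
            elif sa(pos, 4, "WICZ", "WITZ"):
                add("TS", "FX")
                pos += 4
            else:
                pos += 1

        elif c == "X":
            if not (pos == last and (sa(pos - 3, 3, "IAU", "EAU") or sa(pos - 2, 2, "AU", "OU"))):
                add("KS")
            pos += 2 if sa(pos + 1, 1, "C", "X") else 1

        elif c == "Z":
            if ch(pos + 1) == "H":
                add("J")
                pos += 2
            else:
                if sa(pos + 1, 2, "ZO", "ZI", "ZA") or (slavo and pos > 0 and ch(pos - 1) != "T"):
                    add("S", "TS")
                else:
                    add("S")
                pos += 2 if ch(pos + 1) == "Z" else 1

        else:
            pos += 1

    primary = "".join(pri)
    secondary = "".join(sec)
    if maxlength is not None:
        primary = primary[:maxlength]
        secondary = secondary[:maxlength]
    return primary, secondary
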