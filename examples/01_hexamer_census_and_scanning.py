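"""Canonical hexamer census and promoter scanning.

Collapsing each 6-mer with its reverse complement (binding is
strand-symmetric) reduces the 4096 possible hexamers to 2080 canonical
classes.  Scanning slides a 6-bp window over every start position of a
promoter and counts each valid window under its canonical class.
"""

from cishex import canonicalize, enumerate_canonical, scan_sequence

canon = enumerate_canonical()
n_pal = sum(c.is_palindrome for c in canon)
print(f"canonical classes: {len(canon)}  palindromes: {n_pal}  pairs: {len(canon) - n_pal}")

# the classical AuxRE core TGTCTC and its canonical representative
c = canonicalize("TGTCTC")
print(f"TGTCTC canonicalizes to {c.seq} (palindrome: {c.is_palindrome})")

seq = "TGTCTCAAACACGTGAAA"
res = scan_sequence(seq)
print(f"\nscan of {seq!r}: {res.total_positions} windows")
for hexamer, count in sorted(res.position_counts.items()):
    print(f"  {hexamer}: {count}")
# Each line is a canonical hexamer and the number of start positions it
# occupies; note CACGTG (the palindromic G-box) appears exactly once.
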