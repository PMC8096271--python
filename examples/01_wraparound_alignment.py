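"""Count pattern copies in a sequence with wraparound alignment.

The aligner matches a query locally against the infinite cyclic extension of
a short repeat pattern (match +2, mismatch -5, gap -7) and reports the
number of pattern copies the optimal alignment spans.
"""

from vntrkit.repeat import wraparound_align

# a 9-mer repeated 3.5 times with one substitution in the second unit
pattern = "ACGTTGACT"
array = pattern + "ACGTTCACT" + pattern + pattern[:4]

aln = wraparound_align(array, pattern)
print(f"query length : {len(array)} bp")
print(f"pattern      : {pattern} ({len(pattern)} bp)")
print(f"score        : {aln.score}")
print(f"copies       : {aln.copies}")
print(f"aligned span : [{aln.seq_start}, {aln.seq_end})")

# The score reflects 30 matching bases (+2 each) and one mismatch (-5);
# 3.5 copies means the alignment consumed 31-32 pattern positions of the
# 9 bp unit, i.e. the array holds three and a half repeat units.
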