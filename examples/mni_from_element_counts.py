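"""Minimum number of individuals from skeletal element counts.

The MNI bound sorts each element into lefts/rights/unsided per age class,
takes the greatest count per element, and then the maximum over elements
within each age class.  On the bundled jar-coffin assemblage this prints
adult 6 + subadult 3 = 9: at least nine people were interred in the jar.
"""

from paleokin import mni

table = mni.gunsan_jar_coffin_counts()
for element in table.elements:
    vals = mni.per_element_mni(table, element)
    print(f"{element:10s} adult {vals['adult']} subadult {vals['subadult']} "
          f"-> row MNI {vals['combined']}")

totals = mni.total_mni(table)
print(f"\nassemblage MNI: {totals['adult']} adults + "
      f"{totals['subadult']} subadults = {totals['total']} individuals")
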