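<?xml version="1.0" encoding="UTF-8"?>
<uniprot xmlns="http://uniprot.org/uniprot">
  <entry dataset="Swiss-Prot">
    <accession>P00001</accession>
    <name>TEST1_FIXTURE</name>
    <feature type="modified residue" description="Phosphoserine">
      <location>
        <position position="5"/>
      </location>
    </feature>
    <feature type="modified residue" description="Phosphothreonine; by similarity">
      <location>
        <position position="7"/>
      </location>
    </feature>
    <sequence length="10">MKSASPTRLK</sequence>
  </entry>
  <entry dataset="Swiss-Prot">
    <accession>P00002</accession>
    <name>TEST2_FIXTURE</name>
    <feature type="modified residue" description="Phosphotyrosine; potential">
      <location>
        <position position="5"/>
      </location>
    </feature>
    <feature type="modified residue" description="N6-acetyllysine">
      <location>
        <position position="3"/>
      </location>
    </feature>
    <sequence length="10">MAKLYSTWRC</sequence>
  </entry>
  <entry dataset="Swiss-Prot">
    <accession>P00003</accession>
    <name>TEST3_FIXTURE</name>
    <feature type="modified residue" description="Phosphoserine; probable">
      <location>
        <position position="2"/>
      </location>
    </feature>
    <feature type="modified residue" description="Phosphoserine">
      <location>
        <position position="3"/>
      </location>
    </feature>
    <sequence length="10">MSTYKLAGHE</sequence>
  </entry>
</uniprot>
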