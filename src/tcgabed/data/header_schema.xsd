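<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="unqualified">
  <xs:element name="bedSchema">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="field" maxOccurs="unbounded">
          <xs:complexType>
            <xs:attribute name="name" use="required">
              <xs:simpleType>
                <xs:restriction base="xs:string">
                  <xs:pattern value="[A-Za-z_][A-Za-z0-9_]*"/>
                </xs:restriction>
              </xs:simpleType>
            </xs:attribute>
            <xs:attribute name="kind" use="required">
              <xs:simpleType>
                <xs:restriction base="xs:string">
                  <xs:enumeration value="string"/>
                  <xs:enumeration value="integer"/>
                  <xs:enumeration value="float"/>
                  <xs:enumeration value="char"/>
                </xs:restriction>
              </xs:simpleType>
            </xs:attribute>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="experimentType" use="required">
        <xs:simpleType>
          <xs:restriction base="xs:string">
            <xs:enumeration value="cnv"/>
            <xs:enumeration value="dnamethylation"/>
            <xs:enumeration value="dnaseq"/>
            <xs:enumeration value="mirnaseq"/>
            <xs:enumeration value="rnaseq"/>
            <xs:enumeration value="rnaseqv2"/>
          </xs:restriction>
        </xs:simpleType>
      </xs:attribute>
      <xs:attribute name="subtype" use="optional">
        <xs:simpleType>
          <xs:restriction base="xs:string">
            <xs:enumeration value="gene"/>
            <xs:enumeration value="exon"/>
            <xs:enumeration value="spljxn"/>
            <xs:enumeration value="isoform"/>
          </xs:restriction>
        </xs:simpleType>
      </xs:attribute>
    </xs:complexType>
  </xs:element>
</xs:schema>
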