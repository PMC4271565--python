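<?xml version="1.0" encoding="UTF-8"?>
<!-- Schema for nucbond binding-site annotation documents.

     One BindPartner element per complex: per-chain sequence (proSeq /
     dnaSeq / rnaSeq), binding string over '+'/'-' (proBnd / dnaBnd /
     rnaBnd) and author-number index map (proIdx / dnaIdx / rnaIdx),
     followed by one BindingSite element per hydrogen bond. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="qualified">

  <xs:simpleType name="bindingString">
    <xs:restriction base="xs:string">
      <xs:pattern value="[+\-]*"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:complexType name="chainString">
    <xs:simpleContent>
      <xs:extension base="xs:string">
        <xs:attribute name="chain" type="xs:string" use="required"/>
      </xs:extension>
    </xs:simpleContent>
  </xs:complexType>

  <xs:complexType name="chainBindingString">
    <xs:simpleContent>
      <xs:extension base="bindingString">
        <xs:attribute name="chain" type="xs:string" use="required"/>
      </xs:extension>
    </xs:simpleContent>
  </xs:complexType>

  <xs:element name="BindPartner">
    <xs:complexType>
      <xs:sequence>
        <xs:choice minOccurs="0" maxOccurs="unbounded">
          <xs:element name="proSeq" type="chainString"/>
          <xs:element name="proBnd" type="chainBindingString"/>
          <xs:element name="proIdx" type="chainString"/>
          <xs:element name="dnaSeq" type="chainString"/>
          <xs:element name="dnaBnd" type="chainBindingString"/>
          <xs:element name="dnaIdx" type="chainString"/>
          <xs:element name="rnaSeq" type="chainString"/>
          <xs:element name="rnaBnd" type="chainBindingString"/>
          <xs:element name="rnaIdx" type="chainString"/>
        </xs:choice>
        <xs:element name="BindingSite" minOccurs="0" maxOccurs="unbounded">
          <xs:complexType>
            <xs:attribute name="PDBID" type="xs:string" use="required"/>
            <xs:attribute name="Donor" type="xs:string" use="required"/>
            <xs:attribute name="DonorChain" type="xs:string" use="required"/>
            <xs:attribute name="DonorIndex" type="xs:string" use="required"/>
            <xs:attribute name="DonorResidue" type="xs:string" use="required"/>
            <xs:attribute name="Acceptor" type="xs:string" use="required"/>
            <xs:attribute name="AcceptorChain" type="xs:string" use="required"/>
            <xs:attribute name="AcceptorIndex" type="xs:string" use="required"/>
            <xs:attribute name="AcceptorResidue" type="xs:string" use="required"/>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="PDBID" type="xs:string" use="required"/>
    </xs:complexType>
  </xs:element>
</xs:schema>
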