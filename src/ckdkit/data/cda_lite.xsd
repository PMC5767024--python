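<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema"
           xmlns:c="urn:ckdkit:cda-lite:1"
           targetNamespace="urn:ckdkit:cda-lite:1"
           elementFormDefault="qualified">

  <xs:element name="ClinicalDocument">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="header" type="c:Header"/>
        <xs:element name="medications" type="c:Medications"/>
        <xs:element name="allergies" type="c:Allergies"/>
        <xs:element name="labResults" type="c:LabResults"/>
        <xs:element name="riskEvaluation" type="c:RiskEvaluation"/>
        <xs:any namespace="##other" processContents="lax" minOccurs="0" maxOccurs="unbounded"/>
      </xs:sequence>
    </xs:complexType>
  </xs:element>

  <xs:complexType name="Header">
    <xs:sequence>
      <xs:element name="patient">
        <xs:complexType>
          <xs:attribute name="id" type="xs:string" use="required"/>
          <xs:attribute name="gender" use="required">
            <xs:simpleType>
              <xs:restriction base="xs:string">
                <xs:enumeration value="F"/>
                <xs:enumeration value="M"/>
              </xs:restriction>
            </xs:simpleType>
          </xs:attribute>
          <xs:attribute name="age" type="xs:integer" use="required"/>
          <xs:attribute name="weight" type="xs:decimal" use="required"/>
          <xs:attribute name="sah" type="xs:boolean" use="required"/>
          <xs:attribute name="dm" type="xs:boolean" use="required"/>
        </xs:complexType>
      </xs:element>
      <xs:element name="author">
        <xs:complexType>
          <xs:attribute name="id" type="xs:string" use="required"/>
        </xs:complexType>
      </xs:element>
      <xs:element name="effectiveTime" type="xs:dateTime"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="Medications">
    <xs:sequence>
      <xs:element name="medication" minOccurs="0" maxOccurs="unbounded">
        <xs:complexType>
          <xs:attribute name="substance" type="xs:string" use="required"/>
          <xs:attribute name="dose" type="xs:string"/>
          <xs:attribute name="schedule" type="xs:string"/>
        </xs:complexType>
      </xs:element>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="Allergies">
    <xs:sequence>
      <xs:element name="allergy" minOccurs="0" maxOccurs="unbounded">
        <xs:complexType>
          <xs:attribute name="substance" type="xs:string" use="required"/>
          <xs:attribute name="reaction" type="xs:string"/>
        </xs:complexType>
      </xs:element>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="LabResults">
    <xs:sequence>
      <xs:element name="lab" minOccurs="0" maxOccurs="unbounded">
        <xs:complexType>
          <xs:attribute name="name" type="xs:string" use="required"/>
          <xs:attribute name="value" type="xs:decimal" use="required"/>
          <xs:attribute name="unit" type="xs:string" use="required"/>
          <xs:attribute name="date" type="xs:string"/>
        </xs:complexType>
      </xs:element>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="RiskEvaluation">
    <xs:sequence minOccurs="0">
      <xs:element name="proteinuriaCategory" type="xs:string"/>
      <xs:element name="stage" type="xs:string"/>
      <xs:element name="riskLevel" type="xs:string"/>
      <xs:element name="gfr" type="xs:decimal"/>
      <xs:element name="narrative" type="xs:string"/>
      <xs:element name="timestamp" type="xs:dateTime"/>
    </xs:sequence>
    <xs:attribute name="present" type="xs:boolean" use="required"/>
  </xs:complexType>

</xs:schema>
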