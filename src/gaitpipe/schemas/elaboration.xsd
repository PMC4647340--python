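<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="unqualified">

  <xs:simpleType name="positiveDouble">
    <xs:restriction base="xs:double">
      <xs:minExclusive value="0"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:element name="elaboration">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="trials">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="trial" type="xs:string" maxOccurs="unbounded"/>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="filters" minOccurs="0">
          <xs:complexType>
            <xs:attribute name="markerCutoff" type="positiveDouble"/>
            <xs:attribute name="grfCutoff" type="positiveDouble"/>
            <xs:attribute name="maxGap" type="xs:nonNegativeInteger" default="10"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="emg" minOccurs="0">
          <xs:complexType>
            <xs:attribute name="hpCutoff" type="positiveDouble" default="30"/>
            <xs:attribute name="lpCutoff" type="positiveDouble" default="6"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="window">
          <xs:complexType>
            <xs:attribute name="method" use="required">
              <xs:simpleType>
                <xs:restriction base="xs:string">
                  <xs:enumeration value="events"/>
                  <xs:enumeration value="grf-threshold"/>
                  <xs:enumeration value="manual"/>
                </xs:restriction>
              </xs:simpleType>
            </xs:attribute>
            <xs:attribute name="startLabel" type="xs:string" default="Foot Strike"/>
            <xs:attribute name="stopLabel" type="xs:string" default="Foot Off"/>
            <xs:attribute name="threshold" type="positiveDouble" default="20"/>
            <xs:attribute name="minContact" type="positiveDouble" default="0.05"/>
            <xs:attribute name="plates" type="xs:string"/>
            <xs:attribute name="start" type="xs:positiveInteger"/>
            <xs:attribute name="stop" type="xs:positiveInteger"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="outputMarkers" minOccurs="0">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="marker" type="xs:string" maxOccurs="unbounded" minOccurs="0"/>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="maxEmgTrials" minOccurs="0">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="trial" type="xs:string" maxOccurs="unbounded" minOccurs="0"/>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="id" use="required">
        <xs:simpleType>
          <xs:restriction base="xs:string">
            <xs:pattern value="[A-Za-z0-9_\-]+"/>
          </xs:restriction>
        </xs:simpleType>
      </xs:attribute>
      <xs:attribute name="emgFormat" default="mot">
        <xs:simpleType>
          <xs:restriction base="xs:string">
            <xs:enumeration value="mot"/>
            <xs:enumeration value="sto"/>
            <xs:enumeration value="txt"/>
          </xs:restriction>
        </xs:simpleType>
      </xs:attribute>
    </xs:complexType>
  </xs:element>
</xs:schema>
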